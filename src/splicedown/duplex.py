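"""Intermolecular miRNA-target duplex prediction by dynamic programming.

The model considers only base pairs between the two strands (no intramolecular
structure). A duplex is an antiparallel chain of pairs: miRNA position i
(5'->3') pairs target position j, with j decreasing as i increases. Adjacent
pairs contribute a nearest-neighbor stack energy; gaps on one side cost a
bulge penalty and gaps on both sides an interior-loop penalty, each bounded by
the model's size caps. A single duplex-initiation constant is added once.
Allowed pairs are the four Watson-Crick pairs plus the G.U wobble.

Energies are read from a plain-text parameter table
(``data/rna_duplex_params.tsv``); agreement with external hybridization
programs is approximate by construction.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

PAIRS = ("AU", "UA", "CG", "GC", "GU", "UG")
WC_PAIRS = frozenset({"AU", "UA", "CG", "GC"})
WOBBLE_PAIRS = frozenset({"GU", "UG"})
_PAIR_CODE = {p: k for k, p in enumerate(PAIRS)}

#: minimum target length for a hybridization attempt
MIN_TARGET_LEN = 8


def as_rna(seq: str) -> str:
    """Uppercase and transcribe DNA T -> RNA U."""
    return seq.upper().replace("T", "U")


class EnergyModel:
    """Tabulated nearest-neighbor stack energies plus loop penalties."""

    def __init__(self, stack: Dict[Tuple[str, str], float], bulge: Dict[int, float],
                 interior: Dict[int, float], duplex_init: float,
                 max_bulge: int = 15, max_interior: int = 15,
                 interior_asymmetry: float = 0.6,
                 interior_asymmetry_max: float = 3.0):
        if max_bulge < 1 or max_interior < 1:
            raise ValueError("loop size caps must be >= 1")
        if any(v < 0 for v in bulge.values()) or any(v < 0 for v in interior.values()):
            raise ValueError("loop penalties must be non-negative")
        self.duplex_init = float(duplex_init)
        self.max_bulge = int(max_bulge)
        self.max_interior = int(max_interior)
        self.interior_asymmetry = float(interior_asymmetry)
        self.interior_asymmetry_max = float(interior_asymmetry_max)
        self._bulge = dict(bulge)
        self._interior = dict(interior)
        # symmetric closure: reading the duplex from the other end swaps and
        # reverses the two pairs, E(p1,p2) = E(rev p2, rev p1)
        full: Dict[Tuple[str, str], float] = {}
        for (p1, p2), val in stack.items():
            mirror = (p2[::-1], p1[::-1])
            for key in ((p1, p2), mirror):
                if key in full and abs(full[key] - val) > 1e-9:
                    raise ValueError(f"conflicting stack energies for {key}")
                full[key] = float(val)
        missing = [(a, b) for a in PAIRS for b in PAIRS if (a, b) not in full]
        if missing:
            raise ValueError(f"stack table incomplete, missing {missing[:3]}...")
        self._stack = full
        self._stack_matrix = np.array(
            [[full[(a, b)] for b in PAIRS] for a in PAIRS], dtype=float
        )

    def stack_energy(self, p1: str, p2: str) -> float:
        return self._stack[(p1, p2)]

    def bulge_penalty(self, n: int) -> float:
        if not 1 <= n <= self.max_bulge:
            raise ValueError(f"bulge size {n} outside 1..{self.max_bulge}")
        return self._bulge[n]

    def interior_penalty(self, n1: int, n2: int) -> float:
        if not (1 <= n1 <= self.max_interior and 1 <= n2 <= self.max_interior):
            raise ValueError("interior loop side outside cap")
        asym = min(self.interior_asymmetry * abs(n1 - n2), self.interior_asymmetry_max)
        return self._interior[n1 + n2] + asym

    @property
    def stack_matrix(self) -> np.ndarray:
        return self._stack_matrix


def load_energy_model(path: Optional[str] = None) -> EnergyModel:
    """Load the packaged (or a user-supplied) plain-text parameter table."""
    if path is None:
        ref = importlib.resources.files("splicedown").joinpath("data/rna_duplex_params.tsv")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    params: Dict[str, float] = {}
    stack: Dict[Tuple[str, str], float] = {}
    bulge: Dict[int, float] = {}
    interior: Dict[int, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, *rest = line.split("\t")
        if kind == "param":
            params[rest[0]] = float(rest[1])
        elif kind == "stack":
            stack[(rest[0], rest[1])] = float(rest[2])
        elif kind == "bulge":
            bulge[int(rest[0])] = float(rest[1])
        elif kind == "interior":
            interior[int(rest[0])] = float(rest[1])
        else:
            raise ValueError(f"unknown parameter record {kind!r}")
    return EnergyModel(
        stack=stack, bulge=bulge, interior=interior,
        duplex_init=params["duplex_init"],
        max_bulge=int(params.get("max_bulge", 15)),
        max_interior=int(params.get("max_interior", 15)),
        interior_asymmetry=params.get("interior_asymmetry", 0.6),
        interior_asymmetry_max=params.get("interior_asymmetry_max", 3.0),
    )


@lru_cache(maxsize=1)
def default_energy_model() -> EnergyModel:
    return load_energy_model()


@dataclass
class DuplexHit:
    """Best hybridization of one miRNA against one target region."""

    mirna_id: str
    event_id: str
    mfe: float
    #: half-open window on the target region, original (5'->3') orientation
    target_window: Optional[Tuple[int, int]]
    #: per miRNA position 1..L: 'WC', 'wobble' or 'none'
    pairing_map: List[str] = field(default_factory=list)
    #: per miRNA position 1..L: 0-based target index of the partner, or None
    partner_index: List[Optional[int]] = field(default_factory=list)
    seed_class: str = "Unclassified"
    a1_adenosine: bool = False
    a1_edge: bool = False

    @property
    def is_hit(self) -> bool:
        return self.target_window is not None


def _no_hit(mirna_id: str, event_id: str, length: int) -> DuplexHit:
    return DuplexHit(mirna_id, event_id, 0.0, None, ["none"] * length,
                     [None] * length)


def _pair_codes(m: str, r: str) -> np.ndarray:
    codes = np.full((len(m), len(r)), -1, dtype=np.int8)
    for i, a in enumerate(m):
        for j, b in enumerate(r):
            codes[i, j] = _PAIR_CODE.get(a + b, -1)
    return codes


def step_cost(model: EnergyModel, p1: str, p2: str, gap_q: int, gap_t: int) -> float:
    """Energy of extending pair p1 to pair p2 across the given gap sizes."""
    if gap_q == 0 and gap_t == 0:
        return model.stack_energy(p1, p2)
    if gap_t == 0:
        return model.bulge_penalty(gap_q)
    if gap_q == 0:
        return model.bulge_penalty(gap_t)
    return model.interior_penalty(gap_q, gap_t)


def duplex_mfe(
    mirna_seq: str,
    target_seq: str,
    model: Optional[EnergyModel] = None,
    mirna_id: str = "",
    event_id: str = "",
    min_target_len: int = MIN_TARGET_LEN,
) -> DuplexHit:
    """Global minimum-free-energy intermolecular duplex.

    Returns a no-hit result (mfe 0, empty pairing map) when the target is
    shorter than ``min_target_len`` or when no pairing achieves negative
    energy.
    """
    model = model or default_energy_model()
    m = as_rna(mirna_seq)
    t = as_rna(target_seq)
    L, T = len(m), len(t)
    if T < min_target_len or L == 0:
        return _no_hit(mirna_id, event_id, L)
    r = t[::-1]  # reversed target: pairing becomes co-linear
    pc = _pair_codes(m, r)
    valid = pc >= 0
    if not valid.any():
        return _no_hit(mirna_id, event_id, L)

    S = model.stack_matrix
    inf = np.inf
    best = np.full((L, T), inf)
    par_i = np.full((L, T), -1, dtype=np.int32)
    par_j = np.full((L, T), -1, dtype=np.int32)

    # transition list: gap sizes (a in miRNA, b in target) and their loop cost
    loops: List[Tuple[int, int, float]] = []
    for a in range(model.max_bulge + 1):
        for b in range(model.max_bulge + 1):
            if a == 0 and b == 0:
                continue
            if a > 0 and b > 0:
                if a > model.max_interior or b > model.max_interior:
                    continue
                loops.append((a, b, model.interior_penalty(a, b)))
            else:
                loops.append((a, b, model.bulge_penalty(max(a, b))))

    for i in range(L):
        row_valid = valid[i]
        if not row_valid.any():
            continue
        cands = [np.where(row_valid, model.duplex_init, inf)]
        meta: List[Tuple[int, int]] = [(-1, -1)]  # (a, b); (-1,-1) = chain start
        if i >= 1:
            # stack transition (no gaps): previous pair at (i-1, j-1)
            prev = best[i - 1]
            stack_cost = np.full(T, inf)
            cols = np.arange(1, T)
            ok = row_valid[1:] & valid[i - 1, :-1]
            if ok.any():
                jj = cols[ok]
                stack_cost[jj] = prev[jj - 1] + S[pc[i - 1, jj - 1], pc[i, jj]]
            cands.append(stack_cost)
            meta.append((0, 0))
            for a, b, cost in loops:
                ip = i - 1 - a
                if ip < 0:
                    continue
                shift = b + 1
                if shift >= T:
                    continue
                vec = np.full(T, inf)
                vec[shift:] = best[ip][:-shift] + cost
                vec[~row_valid] = inf
                cands.append(vec)
                meta.append((a, b))
        arr = np.vstack(cands)
        choice = np.argmin(arr, axis=0)
        best[i] = arr[choice, np.arange(T)]
        for k, (a, b) in enumerate(meta):
            sel = (choice == k) & np.isfinite(best[i])
            if not sel.any():
                continue
            if a < 0:
                par_i[i, sel] = -1
                par_j[i, sel] = -1
            else:
                js = np.nonzero(sel)[0]
                par_i[i, js] = i - 1 - a
                par_j[i, js] = js - 1 - b

    flat = int(np.argmin(best))
    bi, bj = divmod(flat, T)
    mfe = float(best[bi, bj])
    if not np.isfinite(mfe) or mfe >= 0:
        return _no_hit(mirna_id, event_id, L)

    # traceback to the chain of (miRNA index, reversed-target index) pairs
    chain: List[Tuple[int, int]] = []
    ci, cj = bi, bj
    while ci >= 0:
        chain.append((ci, cj))
        ci, cj = int(par_i[ci, cj]), int(par_j[ci, cj])
    chain.reverse()

    pairing = ["none"] * L
    partner: List[Optional[int]] = [None] * L
    orig = []
    for qi, rj in chain:
        oj = T - 1 - rj
        code = PAIRS[pc[qi, rj]]
        pairing[qi] = "WC" if code in WC_PAIRS else "wobble"
        partner[qi] = oj
        orig.append(oj)
    window = (min(orig), max(orig) + 1)
    return DuplexHit(mirna_id, event_id, round(mfe, 6), window, pairing, partner)


def recompute_energy(hit: DuplexHit, mirna_seq: str, target_seq: str,
                     model: Optional[EnergyModel] = None) -> float:
    """Energy of the reported pairing map under the same model.

    Self-consistency check: equals ``hit.mfe`` to 1e-6 for any hit produced
    by :func:`duplex_mfe`.
    """
    model = model or default_energy_model()
    if not hit.is_hit:
        return 0.0
    m = as_rna(mirna_seq)
    t = as_rna(target_seq)
    paired = [(i, hit.partner_index[i]) for i in range(len(m))
              if hit.partner_index[i] is not None]
    energy = model.duplex_init
    for (i1, j1), (i2, j2) in zip(paired, paired[1:]):
        p1 = m[i1] + t[j1]
        p2 = m[i2] + t[j2]
        gap_q = i2 - i1 - 1
        gap_t = j1 - j2 - 1  # target indices decrease along the miRNA
        energy += step_cost(model, p1, p2, gap_q, gap_t)
    return energy
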