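# Nearest-neighbor RNA/RNA duplex free-energy parameters (kcal/mol, 37 C).
# Watson-Crick stack increments follow Xia et al. 1998; G.U wobble stacks and
# loop initiations follow the Turner 1999/2004 rule set. Loop penalties are
# applied independently of the closing pairs.
#
# stack <p1> <p2> <dG>: p1 = (5' base of strand 1, paired base of strand 2),
# p2 = the next pair toward strand 1's 3' end. The loader completes the table
# with the duplex-reading symmetry E(p1,p2) = E(reverse p2, reverse p1).
param	duplex_init	4.09
param	max_bulge	15
param	max_interior	15
param	interior_asymmetry	0.6
param	interior_asymmetry_max	3.0
stack	AU	AU	-0.93
stack	AU	UA	-1.10
stack	UA	AU	-1.33
stack	AU	CG	-2.24
stack	AU	GC	-2.08
stack	UA	CG	-2.35
stack	UA	GC	-2.11
stack	CG	CG	-3.26
stack	CG	GC	-2.36
stack	GC	CG	-3.42
stack	AU	GU	-0.55
stack	AU	UG	-1.36
stack	UA	GU	-1.00
stack	UA	UG	-1.27
stack	CG	GU	-1.41
stack	CG	UG	-2.11
stack	GC	GU	-1.53
stack	GC	UG	-2.51
stack	GU	GU	-0.50
stack	GU	UG	1.29
stack	UG	GU	-0.30
bulge	1	3.8
bulge	2	2.8
bulge	3	3.2
bulge	4	3.6
bulge	5	4.0
bulge	6	4.4
bulge	7	4.6
bulge	8	4.7
bulge	9	4.8
bulge	10	4.9
bulge	11	5.0
bulge	12	5.1
bulge	13	5.2
bulge	14	5.3
bulge	15	5.4
interior	2	1.0
interior	3	1.4
interior	4	1.7
interior	5	1.8
interior	6	2.0
interior	7	2.2
interior	8	2.3
interior	9	2.4
interior	10	2.5
interior	11	2.6
interior	12	2.7
interior	13	2.8
interior	14	2.9
interior	15	3.0
interior	16	3.0
interior	17	3.1
interior	18	3.2
interior	19	3.2
interior	20	3.3
interior	21	3.3
interior	22	3.4
interior	23	3.4
interior	24	3.5
interior	25	3.5
interior	26	3.5
interior	27	3.6
interior	28	3.6
interior	29	3.6
interior	30	3.7
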