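# Bond-valence parameters for Mn-ligand bonds: v_i = exp((R0 - R_i)/B).
# EXTERNAL REFERENCE DATA, not derived from this package's training pipeline.
# R0/B values from the standard bond-valence compilations:
#   I. D. Brown & D. Altermatt, Acta Cryst. B41 (1985) 244-247
#   N. E. Brese & M. O'Keeffe, Acta Cryst. B47 (1991) 192-197
# Edit or extend freely; the loader accepts any (state, element, R0, B) rows.
# state	element	R0	B	source
2	O	1.790	0.37	brown-altermatt-1985
2	N	1.849	0.37	brese-okeeffe-1991
3	O	1.760	0.37	brown-altermatt-1985
3	N	1.837	0.37	brese-okeeffe-1991
4	O	1.753	0.37	brown-altermatt-1985
4	N	1.822	0.37	brese-okeeffe-1991
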