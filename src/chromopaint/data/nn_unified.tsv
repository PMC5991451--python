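# Unified nearest-neighbor parameters for DNA/DNA duplexes in 1 M NaCl
# (SantaLucia, PNAS 95:1460-1465, 1998).  dH in kcal/mol, dS in cal/(mol*K).
# "stack" keys are the 5'->3' top-strand dinucleotide; the table is closed
# under reverse complement (e.g. CA == TG).
# kind	key	dH	dS
stack	AA	-7.9	-22.2
stack	AC	-8.4	-22.4
stack	AG	-7.8	-21.0
stack	AT	-7.2	-20.4
stack	CA	-8.5	-22.7
stack	CC	-8.0	-19.9
stack	CG	-10.6	-27.2
stack	CT	-7.8	-21.0
stack	GA	-8.2	-22.2
stack	GC	-9.8	-24.4
stack	GG	-8.0	-19.9
stack	GT	-8.4	-22.4
stack	TA	-7.2	-21.3
stack	TC	-8.2	-22.2
stack	TG	-8.5	-22.7
stack	TT	-7.9	-22.2
init	GC	0.1	-2.8
init	AT	2.3	4.1
sym	SYM	0.0	-1.4
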