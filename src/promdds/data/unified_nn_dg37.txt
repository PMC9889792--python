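# Unified nearest-neighbor free-energy parameters for DNA duplex stability.
# Delta-G at 37 C, 1 M NaCl, in kcal/mol per dinucleotide stack
# (5'->3' top strand; the table is closed under reverse complement).
# More negative = more stable duplex. Source: unified oligonucleotide
# nearest-neighbor thermodynamics (SantaLucia, PNAS 1998).
AA: -1.00
AC: -1.44
AG: -1.28
AT: -0.88
CA: -1.45
CC: -1.84
CG: -2.17
CT: -1.28
GA: -1.30
GC: -2.24
GG: -1.84
GT: -1.44
TA: -0.58
TC: -1.30
TG: -1.45
TT: -1.00
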