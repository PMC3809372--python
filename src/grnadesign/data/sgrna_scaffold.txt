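# Canonical S. pyogenes sgRNA scaffold (tracrRNA fusion), appended 3' of the
# 20-nt guide before secondary-structure prediction.  Edit or replace via the
# --scaffold CLI flag / FoldParams(scaffold=...).
GUUUUAGAGCUAGAAAUAGCAAGUUAAAAUAAGGCUAGUCCGUUAUCAACUUGAAAAAGUGGCACCGAGUCGGUGCUUUU
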