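# Proposition-bearing dependency relations for DEPID / DEPID-R.
# One relation label per line; lines starting with '#' are comments.
# Defaults cover verb/adjective/adverb predicates and core arguments;
# determiners, case markers, auxiliaries etc. do not carry propositions.
nsubj
csubj
obj
iobj
obl
ccomp
xcomp
advcl
acl
advmod
amod
appos
nmod
nummod
conj
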