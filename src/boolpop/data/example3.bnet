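# Three-node demonstration network: A is inhibited by B, B needs both A and
# C, C needs either A or B.  Its closure from {A} is the canonical worked
# example of the product-basis construction.
targets, factors
A, !B
B, A & C
C, A | B
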