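# Six-node feedforward "ladder" toy: a self-sustaining input drives two
# marker branches (MA, MB) and a delayed inhibitor (INH) that shuts both
# outputs off.  Wild-type co-activation of OA and OB is therefore transient;
# persistent co-activation requires a loss-of-function of INH, which makes
# this fixture a miniature knockout-screen testbed.
targets, factors
IN, IN
MA, IN
MB, IN
INH, IN
OA, MA & !INH
OB, MB & !INH
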