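# ATC prefix -> antihypertensive drug class. Longest-prefix match wins,
# so the fixed-combination codes below beat their shorter single-class parents.
C09A	ACE_INHIBITOR
C09C	ARB
C07	BETA_BLOCKER
C08	CCB
C03A	DIURETIC
C03B	DIURETIC
C03D	DIURETIC
C03E	DIURETIC
C07FB02	FIXED_COMBINATION
C09BA	FIXED_COMBINATION
C09D	FIXED_COMBINATION
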