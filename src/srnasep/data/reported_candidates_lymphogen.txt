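let-7f-1
let-7f-2
mir-15a
mir-16-1
mir-92a-1
mir-92a-2
mir-183
let-7g
mir-15b
mir-23b
mir-130a
mir-142
mir-191
mir-126
mir-296
mir-331
mir-425
mir-451a
mir-92b
mir-574
mir-4286
mir-4454
ENST00000516594
ENST00000363271
ENST00000459091
ENST00000516350
ENST00000517209
ENST00000516507
ENST00000363865
ENST00000362808
ENST00000364409
ENST00000363745
ENST00000461337
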