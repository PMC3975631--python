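let-7a-1
let-7a-2
let-7a-3
let-7b
let-7d
let-7f-1
let-7f-2
mir-18a
mir-92a-1
mir-92a-2
mir-99a
let-7g
mir-30b
mir-130a
mir-191
mir-29c
mir-296
mir-378a
mir-326
mir-331
mir-339
mir-425
mir-451a
mir-92b
mir-574
mir-660
mir-664
mir-4286
mir-4454
ENST00000365160
ENST00000387347
ENST00000482884
ENST00000459949
ENST00000410361
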