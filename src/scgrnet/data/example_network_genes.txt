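# synthetic 40-gene example network (fixture, not a real gene set)
GENE01
GENE02
GENE03
GENE04
GENE05
GENE06
GENE07
GENE08
GENE09
GENE10
GENE11
GENE12
GENE13
GENE14
GENE15
GENE16
GENE17
GENE18
GENE19
GENE20
GENE21
GENE22
GENE23
GENE24
GENE25
GENE26
GENE27
GENE28
GENE29
GENE30
GENE31
GENE32
GENE33
GENE34
GENE35
GENE36
GENE37
GENE38
GENE39
GENE40
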