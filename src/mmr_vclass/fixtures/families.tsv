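family_id
F_051
F_161
F_176
F_326
F_376
F_058
F_149
F_138
F_315
F_008
F_132
F_156
F_143
F_328
F_202
F_395
F_089
F_046
F_263
F_193
F_170
F_111
F_240
F_352
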