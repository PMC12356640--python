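taxon,age_Ma
Oceanotitan,147
Euhelopus,125
Ligabuesaurus,112
Jainosaurus,68
Dreadnoughtus,77
Antarctosaurus,72
Bonitasaura,85
Mendozasaurus,88
Muyelensaurus,87
Aeolosaurus,72
Ampelosaurus,70
Lirainosaurus,72
Lohuecotitan,73
Bonatitan,68
Magyarosaurus,68
Neuquensaurus,80
Saltasaurus,70
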