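(Oceanotitan,(Euhelopus,(Ligabuesaurus,((Jainosaurus,Dreadnoughtus),(Antarctosaurus,((Bonitasaura,(Mendozasaurus,Muyelensaurus)),(Aeolosaurus,(Ampelosaurus,Lirainosaurus),(Lohuecotitan,(Bonatitan,(Magyarosaurus,(Neuquensaurus,Saltasaurus)))))))))));
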