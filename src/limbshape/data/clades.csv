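clade,taxon
Titanosauriformes,Euhelopus
Titanosauriformes,Ligabuesaurus
Titanosauriformes,Jainosaurus
Titanosauriformes,Dreadnoughtus
Titanosauriformes,Antarctosaurus
Titanosauriformes,Bonitasaura
Titanosauriformes,Mendozasaurus
Titanosauriformes,Muyelensaurus
Titanosauriformes,Aeolosaurus
Titanosauriformes,Ampelosaurus
Titanosauriformes,Lirainosaurus
Titanosauriformes,Lohuecotitan
Titanosauriformes,Bonatitan
Titanosauriformes,Magyarosaurus
Titanosauriformes,Neuquensaurus
Titanosauriformes,Saltasaurus
Somphospondyli,Ligabuesaurus
Somphospondyli,Jainosaurus
Somphospondyli,Dreadnoughtus
Somphospondyli,Antarctosaurus
Somphospondyli,Bonitasaura
Somphospondyli,Mendozasaurus
Somphospondyli,Muyelensaurus
Somphospondyli,Aeolosaurus
Somphospondyli,Ampelosaurus
Somphospondyli,Lirainosaurus
Somphospondyli,Lohuecotitan
Somphospondyli,Bonatitan
Somphospondyli,Magyarosaurus
Somphospondyli,Neuquensaurus
Somphospondyli,Saltasaurus
Titanosauria,Jainosaurus
Titanosauria,Dreadnoughtus
Titanosauria,Antarctosaurus
Titanosauria,Bonitasaura
Titanosauria,Mendozasaurus
Titanosauria,Muyelensaurus
Titanosauria,Aeolosaurus
Titanosauria,Ampelosaurus
Titanosauria,Lirainosaurus
Titanosauria,Lohuecotitan
Titanosauria,Bonatitan
Titanosauria,Magyarosaurus
Titanosauria,Neuquensaurus
Titanosauria,Saltasaurus
Lithostrotia,Antarctosaurus
Lithostrotia,Bonitasaura
Lithostrotia,Mendozasaurus
Lithostrotia,Muyelensaurus
Lithostrotia,Aeolosaurus
Lithostrotia,Ampelosaurus
Lithostrotia,Lirainosaurus
Lithostrotia,Lohuecotitan
Lithostrotia,Bonatitan
Lithostrotia,Magyarosaurus
Lithostrotia,Neuquensaurus
Lithostrotia,Saltasaurus
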