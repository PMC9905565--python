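# Genus-level checklist of Collembola names used for offline taxonomic
# harmonization. Names only; a small static subset of the genera commonly
# reported in soil community surveys, so tests run without network access.
Acherontiella
Allacma
Anurida
Anurophorus
Appendisotoma
Arrhopalites
Bourletiella
Brachystomella
Ceratophysella
Cryptopygus
Cyphoderus
Desoria
Deuterosminthurus
Dicyrtoma
Dicyrtomina
Entomobrya
Folsomia
Folsomides
Friesea
Heteromurus
Hypogastrura
Isotoma
Isotomiella
Isotomurus
Kalaphorura
Lepidocyrtus
Megalothorax
Mesaphorura
Metaphorura
Micranurida
Neanura
Neelides
Neelus
Onychiurus
Orchesella
Paratullbergia
Parisotoma
Podura
Pogonognathellus
Protaphorura
Pseudachorutes
Pseudisotoma
Pseudosinella
Ptenothrix
Schoettella
Seira
Sminthurides
Sminthurinus
Sminthurus
Sphaeridia
Stenaphorura
Supraphorura
Tetracanthella
Tomocerus
Tullbergia
Vertagopus
Willemia
Willowsia
Xenylla
Xenyllodes
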