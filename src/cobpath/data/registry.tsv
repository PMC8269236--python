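family_id	annotation	pathways	homolog_family_ids
cobA	Uroporphyrinogen-III c-methyltransferase	precorrin2;anaerobic;salvage_remodeling	cysG
hemA	Glutamyl-tRNA reductase	precorrin2
hemB	Delta-aminolevulinic acid dehydratase	precorrin2
hemC	Porphobilinogen deaminase	precorrin2
hemD	Porphyrin biosynthesis protein HemD	precorrin2
hemL	Glutamate-1-semialdehyde 2,1-aminomutase	precorrin2
cysG	Siroheme synthase	precorrin2	cobA
gltX	Glutamate-tRNA ligase	precorrin2
cobB	Hydrogenobyrinate a,c-diamide synthase	aerobic
cobC-beta	Threonine-phosphate decarboxylase	aerobic
cobD	Threonine-phosphate decarboxylase	aerobic;anaerobic
cobF	Precorrin-6A synthase	aerobic
cobG	Precorrin-3B synthase	aerobic
cobH	Precorrin-8X methylmutase	aerobic	cbiC
cobI	Precorrin-2 C(20)-methyltransferase	aerobic
cobJ	Precorrin-3B C(17)-methyltransferase	aerobic	cbiH
cobK	Precorrin-6A reductase	aerobic
cobL	Precorrin-6Y C(5,15)-methyltransferase	aerobic
cobM	Precorrin-4 C(11)-methyltransferase	aerobic	cbiF
cobN	Aerobic cobaltochelatase subunit CobN	aerobic
cobO	Corrinoid adenosyltransferase	aerobic;salvage_remodeling
cobP	Bifunctional adenosylcobalamin biosynthesis protein CobP	aerobic;salvage_remodeling;post_adocbip
cobQ	Cobyric acid synthase	aerobic
cobR	Cob(II)yrinic acid a,c-diamide reductase	aerobic	cbiH
cobS-co	Aerobic cobaltochelatase subunit CobS	aerobic
cobT-co	Aerobic cobaltochelatase subunit CobT	aerobic
cobU-ade	Bifunctional adenosylcobalamin biosynthesis protein CobU	anaerobic;salvage_remodeling;post_adocbip
cbiA	Cobyrinate a,c-diamide synthase	anaerobic
cbiB	Cobalamin biosynthesis protein CbiB	anaerobic;salvage_remodeling
cbiC	Cobalt-precorrin-8 methylmutase	anaerobic	cobH
cbiD	Cobalt-precorrin-5B C(1)-methyltransferase	anaerobic
cbiE	Cobalt-precorrin-7 C(5)-methyltransferase	anaerobic
cbiF	Cobalt-precorrin-4 C(11)-methyltransferase	anaerobic	cobM
cbiG	Cobalt-precorrin-5A hydrolase	anaerobic
cbiH	Cobalt-factor III C(17)-methyltransferase	anaerobic	cobR;cobJ
cbiJ	Cobalt-precorrin-6A reductase	anaerobic
cbiK	Sirohydrochlorin cobaltochelatase	anaerobic
cbiL	Cobalt-precorrin-2 C(20)-methyltransferase	anaerobic
cbiP	Cobyric acid synthase	anaerobic
cbiT	Cobalt-precorrin-6B C(15)-methyltransferase	anaerobic
cbiX	Sirohydrochlorin cobaltochelatase	anaerobic
btuR	Cob(I)alamin adenosyltransferase	anaerobic
pduX	l-threonine kinase	anaerobic
btuB	Vitamin B12 transporter BtuB	salvage_remodeling
btuC	Vitamin B12 import system permease protein BtuC	salvage_remodeling
btuD	Vitamin B12 import ATP-binding protein BtuD	salvage_remodeling
btuF	Vitamin B12-binding protein	salvage_remodeling
cobY	Adenosylcobinamide phosphate guanylyltransferase	salvage_remodeling
cbiZ	Adenosylcobinamide amidohydrolase	salvage_remodeling
eutT	Ethanolamine utilization cobalamin adenosyltransferase	salvage_remodeling
pduO	Corrinoid adenosyltransferase	salvage_remodeling;post_adocbip
cobC-ado	Adenosylcobalamin phosphatase	post_adocbip
cobS-gdp	Adenosylcobinamide GDP ribazoletransferase	post_adocbip
cobT-alpha	Nicotinate-nucleotide-dimethylbenzimidazole phosphoribosyltransferase	post_adocbip
cobU-alpha	Nicotinate-nucleotide-dimethylbenzimidazole phosphoribosyltransferase	post_adocbip
cobV	Adenosylcobinamide GDP ribazoletransferase	post_adocbip
pduS	Cob(II)alamin reductase	post_adocbip
fre	NAD(P)H-flavin reductase	post_adocbip
ubiB	Aquacobalamin reductase	post_adocbip
bluB	5,6-dimethylbenzimidazole synthase	post_adocbip
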