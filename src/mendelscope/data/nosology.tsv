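category	disorder	species	breeds	gene	moi	variant_kinds	omia_id	horn_trait	notes
FGFR3-related chondrodysplasias	Chondrodysplasia	Bos taurus	Holstein	FGFR3	AD	nonsense	001703-9913	0
FGFR3-related chondrodysplasias	Chondrodysplasia (SLS)	Ovis aries	Suffolk	FGFR3	AR	missense	001703-9940	0
Type 2 collagen disorders	Achondrogenesis, type II	Bos taurus	Holstein,crossbred	COL2A1	AD	splice site,missense,large deletion	001926-9913	0
Osteogenesis imperfecta and bone fragility group	Osteogenesis imperfecta type II	Bos taurus	Fleckvieh,Red Angus,Holstein	COL1A1	AD	small indel,missense	002127-9913	0
Disorders of bone mineralisation	Hypophosphatemic rickets	Ovis aries	Corriedale	DMP1	AR	nonsense	001542-9940	0
Disorders of bone mineralisation	Hypophosphatasia	Ovis aries		ALPL	AR	missense	002162-9940	0	genetically-modified organism entry
Disorders of bone mineralisation	Osteopetrosis with gingival hamartomas	Bos taurus	Belgian Blue	CLCN7	AR	missense	001887-9913	0
Sulfation disorders	Osteopetrosis	Bos taurus	Red Angus	SLC4A2	AR	large deletion	002443-9913	0
Sulfation disorders	Complex vertebral malformation	Bos taurus	Holstein	SLC35A3	AR	missense	001340-9913	0
Sulfation disorders	Chondrodysplasia	Ovis aries	Texel	SLC13A1	AR	small deletion	001400-9940	0
Filamins and related disorders	Skeletal-cardio-enteric dysplasia	Bos taurus	Romagnola	MAP2K2	AD	missense	002381-9913	0
Primordial dwarfism and slender bones group	Arachnomelia	Bos taurus	Fleckvieh	MOCS1	AR	frameshift deletion	001541-9913	0
Primordial dwarfism and slender bones group	Arachnomelia	Bos taurus	Brown Swiss	SUOX	AR	frameshift insertion	000059-9913	0
Primordial dwarfism and slender bones group	Caudal vertebral scoliosis (Crooked tail)	Bos taurus	Belgian Blue	MRC2	AR	frameshift deletion	001452-9913	0
Primordial dwarfism and slender bones group	Primordial dwarfism	Bos taurus	Angus	PRKG2	AR	nonsense	001485-9913	0
Primordial dwarfism and slender bones group	Primordial disproportionate dwarfism	Bos taurus	Fleckvieh	GON4L	AR	frameshift deletion	001985-9913	0
Primordial dwarfism and slender bones group	Lethal multi-organ developmental dysplasia (paunch calf syndrome)	Bos taurus	Romagnola,Marchigiana	KDM2B	AR	missense	001722-9913	0
Primordial dwarfism and slender bones group	Caprine-like generalized hypoplasia syndrome	Bos taurus	Montbeliarde	CEP250	AR	nonsense	001502-9913	0
Proteoglycan core proteins disorders	Spondyloepimetaphyseal dysplasia	Bos taurus	Dexter,Scottish Highland	ACAN	AR	frameshift insertion,regulatory	001271-9913	0
Chondrodysplasia punctata (CDP) group	Rhizomelic chondrodysplasia punctata	Bos taurus	Aubrac	GNPAT	AR	splicing	002958-9913	0
Pseudoachondroplasia and the multiple epiphyseal dysplasias	Achondroplasia	Ovis aries	Cheviot	PRICKLE1	AR	small deletion	002693-9940	0
Skeletal disorders caused by abnormalities of cilia or ciliary signaling	Ellis-van Creveld Syndrome	Bos taurus	Tyrolean Grey,Japanese Brown	EVC2	AR	frameshift deletion,splice site,frameshift insertion	002540-9913	0
Spondyloepi(meta)physeal dysplasias (SE(M)D)	Hereditary perinatal weak calf syndrome	Bos taurus	Japanese Black	IARS	AR	missense	001817-9913	0
Polydactyly-Syndactyly-Triphalangism	Syndactyly	Bos taurus	Simmental Charolais cross,Simmental,Angus,Holstein	LRP4	AR	missense,splice site,indel	000963-9913	0
Limb hypoplasia - reduction defects group	Tetradysmelia	Bos taurus	Holstein	RSPO2	AR	frameshift deletion	002297-9913	0
Limb hypoplasia - reduction defects group	Tibial hemimelia syndrome	Bos taurus	Shorthorn,Galloway	ALX4	AR	large deletion,duplication	001009-9913	0
Overgrowth (tall stature) syndromes and segmental overgrowth	Marfan syndrome	Bos taurus	Limousin,Japanese Black	FBN1	AD	missense,splice site	000628-9913	0
Overgrowth (tall stature) syndromes and segmental overgrowth	Skeletal dysplasia, disproportional tall stature	Bos taurus	Japanese Black,Mishima	FGD3	AID	small deletion insertion	002625-9913	0
Overgrowth (tall stature) syndromes and segmental overgrowth	Long tail	Ovis aries	Merinolandschaf	HOXB13	AD	large insertion	002721-9940	0
Genetic inflammatory or rheumatoid-like osteoarthropathies	Dwarfism with inflammatory lesions	Bos taurus	Belgian Blue	RNF11	AR	splice site	001686-9913	0
Dysplasias with multiple joint dislocations	Arthrogryposis multiplex congenita	Bos taurus	Red Dane	CHRNB1	AR	small deletion	002022-9913	0
Dysplasias with multiple joint dislocations	Arthrogryposis multiplex congenita	Bos taurus	Angus	AGRN	AR	large deletion	002135-9913	0
Dysplasias with multiple joint dislocations	Arthrogryposis, lethal syndrome	Bos taurus	Belgium Blue	PIGH	AR	splice site	001953-9913	0
Dysplasias with multiple joint dislocations	Arthrogryposis, distal type 1B	Bos taurus	Holstein	MYBPC1	AD	missense	001978-9913	0
Syndromes featuring craniosynostosis	Facial dysplasia syndrome	Bos taurus	Holstein	FGFR2	AD	missense	002090-9913	0
Syndromes featuring craniosynostosis	Frontonasal dysplasia	Bos taurus	Limousin	ZIC2	AD	frameshift deletion	002307-9913	0
Syndromes featuring craniosynostosis	Otocephaly	Ovis aries	Istrian Pramenka	OTX2	AD	nonsense	002227-9940	0
Craniofacial Dysostoses	Hemifacial microsomia	Bos taurus	Romagnola	LAMB1	AR	missense	002479-9913	0
Craniofacial Dysostoses	Cleft palate	Bos taurus	Limousin	MYH3	AR	small deletion	002590-9913	0
Craniofacial Dysostoses	Mandibulofacial dysostosis	Bos taurus	Hereford	CYP26C1	AR	missense	002288-9913	0
Craniofacial Dysostoses	Brachygnathia	Bos taurus	Brown Swiss	WNT10B	AR	duplication	002759-9913	0
Craniofacial Dysostoses	Brachygnathia, cardiomegaly and renal hypoplasia syndrome	Ovis aries	Merino	OBSL1	AR	small deletion	001595-9940	0
Agenesis, hypoplasia or splitting of the bony core of the horn with or without skull malformations	Polled and multisystemic syndrome	Bos taurus	Charolais,Fleckvieh	ZEB2	AD	frameshift deletion,large deletion	001736-9913	1
Agenesis, hypoplasia or splitting of the bony core of the horn with or without skull malformations	Scurs, type 2	Bos taurus	Charolais	TWIST1	AD	duplication	001593-9913	1
Agenesis, hypoplasia or splitting of the bony core of the horn with or without skull malformations	Polled/Horns, Celtic	Bos taurus	Angus,Galloway	POLLED	AD	complex rearrangement	000483-9913	1	locus rather than a single gene
Agenesis, hypoplasia or splitting of the bony core of the horn with or without skull malformations	Polled/Horns, Friesian	Bos taurus	Holstein	POLLED	AD	duplication	000483-9913	1	locus rather than a single gene
Agenesis, hypoplasia or splitting of the bony core of the horn with or without skull malformations	Polled/Horns, Mongolian	Bos taurus	Kazakh	POLLED	AD	complex rearrangement	000483-9913	1	locus rather than a single gene
Agenesis, hypoplasia or splitting of the bony core of the horn with or without skull malformations	Polled/Horns, Guarani	Bos taurus	Nelore	POLLED	AD	duplication	000483-9913	1	locus rather than a single gene
Agenesis, hypoplasia or splitting of the bony core of the horn with or without skull malformations	Polled	Ovis aries	across breeds	RXFP2	AD	large insertion	000483-9940	1
Agenesis, hypoplasia or splitting of the bony core of the horn with or without skull malformations	Polyceraty	Ovis aries	Damara,Jacob,Navajo-Churro,Sishui	HOXD1	AcD	small deletion	000806-9940	1
Vertebral and costal dysostoses	Brachyspina	Bos taurus	Holstein	FANCI	AR	large deletion	000151-9913	0
Vertebral and costal dysostoses	Vertebral and spinal dysplasia	Bos taurus	Holstein	TBXT	AD	missense	001951-9913	0
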