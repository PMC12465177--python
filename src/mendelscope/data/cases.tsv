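category	disorder	species	breeds	gene	moi	variant_kinds	classification	case_ids	notes
Type 2 collagen disorders	Achondrogenesis, type II	Bos taurus	Holstein	COL2A1	AD	heterozygous,small frameshift deletion	pathogenic	1	table prints small frameshift deletion; the narrative describes a 12-bp in-frame deletion of four residues
Type 2 collagen disorders	Achondrogenesis, type II	Ovis aries	Crossbred	COL2A1	AD	heterozygous,missense	pathogenic	2,3,4,5,6,7	transmitted by a germline-mosaic sire
Osteogenesis imperfecta and bone fragility group	Osteogenesis imperfecta	Bos taurus	Holstein	PPIB	AR	homozygous,intronic	uncertain	8
Osteogenesis imperfecta and bone fragility group	Osteogenesis imperfecta	Bos taurus	Stabiliser	COL1A2	AD	heterozygous,missense	pathogenic	9,10
Osteogenesis imperfecta and bone fragility group	Osteogenesis imperfecta	Ovis aries	Crossbred	COL1A1	AD	heterozygous,missense	pathogenic	11,12,13	transmitted by a germline-mosaic sire
Osteopetrosis and related osteoclast disorders	Osteopetrosis and brachignatia inferior	Bos taurus	Crossbred	LOC112445140	XLD	heterozygous,stop gained	pathogenic	14
Sulfation disorders	Caudal and thoracic vertebral and viscerocranial malformations	Bos taurus	Holstein	SLC40A1	AD	heterozygous,missense	pathogenic	15
Primordial dwarfism and slender bones group	Primordial proportionate dwarfism	Bos taurus	Simmental		unknown		none	16
Primordial dwarfism and slender bones group	Primordial proportionate dwarfism	Bos taurus	Simmental	PTPN9	AD	heterozygous,missense	uncertain	17
Primordial dwarfism and slender bones group	Primordial disproportionate dwarfism	Bos taurus	Angus	PRDM10	AD	heterozygous,missense	pathogenic	18,19
Primordial dwarfism and slender bones group	Primordial disproportionate dwarfism	Bos taurus	Holstein		unknown		none	20
Primordial dwarfism and slender bones group	Primordial disproportionate dwarfism with craniofacial dysmorphism	Bos taurus	Holstein	PDGFRA	AD	heterozygous,missense	pathogenic	21
Primordial dwarfism and slender bones group	Primordial disproportionate dwarfism	Bos taurus	Crossbred	ABCC8	AD	heterozygous,missense	likely_pathogenic	22	table says disproportionate; the narrative calls the same case proportionate
Primordial dwarfism and slender bones group	Arachnomelia	Bos taurus	Holstein		unknown		none	23
Primordial dwarfism and slender bones group	Craniofacial dysmorphism-hydrocephalus-dwarfism syndrome	Bos taurus	Angus		AD	aneuploidy	pathogenic	24	trisomy of chromosome 23, paternal origin
Polydactyly-Syndactyly-Triphalangism	Polydactyly	Bos taurus	Crossbred		AD	aneuploidy	pathogenic	25	partial monosomy of chromosome 28 (~2.7 Mb terminal), paternal origin
Polydactyly-Syndactyly-Triphalangism	Syndactyly	Bos taurus	Holstein	LRP4	AR	compound heterozygous,small frameshift insertion,missense	pathogenic	26
Polydactyly-Syndactyly-Triphalangism	Syndactyly	Bos taurus	Holstein	LRP4	AR	compound heterozygous,small frameshift insertion,missense	pathogenic	27
Polydactyly-Syndactyly-Triphalangism	Syndactyly	Bos taurus	Holstein	KMT2C	AR	homozygous,missense	uncertain	28
Polydactyly-Syndactyly-Triphalangism	Syndactyly	Bos taurus	Droughtmaster	CD4	AR	homozygous,missense	uncertain	29	sire homozygous wildtype; parentage control not possible
Disorders of bone mineralisation	Congenital rickets	Bos taurus	Angus		unknown		none	30,31
Dysplasias with multiple joint dislocations	Craniofacial dysmorphisms, and forelimbs skeletal dysplasia	Bos taurus	Holstein	CCT3	AD	heterozygous,missense	likely_pathogenic	32
Dysplasias with multiple joint dislocations	Craniofacial dysmorphisms, forelimbs dislocations and skeletal dysplasia	Bos taurus	Holstein	ITGAE	AR	homozygous,missense	likely_pathogenic	33
Dysplasias with multiple joint dislocations	Craniofacial dysmorphism, forelimbs dysplasia with joint contracture	Bos taurus	Chianina	CNTNAP1	AR	compound heterozygous,missense,intronic	likely_pathogenic	34
Dysplasias with multiple joint dislocations	Forelimbs dysplasia with joint contracture	Bos taurus	Holstein	NFE2L1	AD	heterozygous,small disruptive inframe deletion	likely_pathogenic	35
Dysplasias with multiple joint dislocations	Forelimbs dysplasia with joint contracture	Bos taurus	Chianina	IL16	AD	heterozygous,missense	likely_pathogenic	36
Dysplasias with multiple joint dislocations	Forelimbs dysplasia with joint contracture	Bos taurus	Limousin		unknown		none	37,38
Vertebral and costal dysostoses	Hemifacial microsomia with hemivertebrae	Bos taurus	Rendena		unknown		none	39
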