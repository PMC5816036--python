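pathway_name	trait_name	csr_class	provenance
Biosynthesis of type II polyketide backbone	Biosynthesis of type II polyketide backbone	C	curated: antimicrobial secondary-metabolite production (neighbor inhibition)
Biosynthesis of type II polyketide products	Biosynthesis of type II polyketide products	C	curated: antimicrobial secondary-metabolite production (neighbor inhibition)
Clavulanic acid biosynthesis	Clavulanic acid biosynthesis	C	curated: beta-lactamase-inhibitor production (neighbor inhibition)
Carbapenem biosynthesis	Carbapenem biosynthesis	C	curated: antibiotic production (neighbor inhibition)
Biosynthesis of siderophore group nonribosomal peptides	Biosynthesis of siderophore group nonribosomal peptides	C	curated: siderophore monopolization of iron (resource capture)
Acarbose and validamycin biosynthesis	Acarbose and validamycin biosynthesis	C	curated: glycosidase-inhibitor production (neighbor inhibition)
Polyketide sugar unit biosynthesis	Polyketide sugar unit biosynthesis	C	curated: precursor supply for antimicrobial polyketides
Staurosporine biosynthesis	Staurosporine biosynthesis	C	curated: bioactive alkaloid production (neighbor inhibition)
ABC transporters	ABC transporters	conditional_CS	curated: conditionally C (resource-capture transporters) or S (efflux/protective transporters); tallied under both C and S
Porphyrin and chlorophyll metabolism	Porphyrin and chlorophyll metabolism	S	curated: cofactor/pigment metabolism mitigating cellular damage
Proteasome	Proteasome	S	curated: turnover of damaged proteins (damage mitigation)
Ascorbate and aldarate metabolism	Ascorbate and aldarate metabolism	S	curated: antioxidant metabolism (free-radical scavenging)
Mismatch repair	Mismatch repair	S	curated: DNA-repair capacity (damage mitigation)
Thiamine metabolism	Thiamine metabolism	S	curated: stress-linked cofactor metabolism
Carbon metabolism	Central carbon metabolism	R	curated: central metabolic flux (growth potential); tallied jointly with TCA cycle as one central-carbon trait
TCA cycle	Central carbon metabolism	R	curated: central metabolic flux (growth potential); tallied jointly with Carbon metabolism as one central-carbon trait
Biosynthesis of amino acids	Biosynthesis of amino acids	R	curated: growth-limiting anabolic capacity
Carbon-fixation pathways in prokaryotes	Carbon-fixation pathways in prokaryotes	R	curated: growth-limiting metabolic capacity
Oxidative phosphorylation	Oxidative phosphorylation	R	curated: energy generation for rapid growth
2-Oxocarboxylic acid metabolism	2-Oxocarboxylic acid metabolism	R	curated: central metabolic flux (growth potential)
Aminoacyl-tRNA biosynthesis	Aminoacyl-tRNA biosynthesis	R	curated: translation capacity (reproduction-limiting)
Pyrimidine metabolism	Pyrimidine metabolism	R	curated: nucleotide production (reproduction-limiting)
Ribosome	Ribosome	R	curated: ribosome production potential (reproduction-limiting)
One carbon pool by folate	One carbon pool by folate	R	curated: nucleotide/methylation precursor supply (growth potential)
Bacterial chemotaxis	Bacterial chemotaxis	foraging	synthetic stand-in: representative foraging pathway (chemotaxis); outside the CSR axes
Flagellar assembly	Flagellar assembly	foraging	synthetic stand-in: representative foraging pathway (motility); outside the CSR axes
Two-component system	Two-component system	foraging	synthetic stand-in: representative foraging pathway (environmental sensing/plasticity); outside the CSR axes
Quorum sensing	Quorum sensing	foraging	synthetic stand-in: representative foraging pathway (plasticity); outside the CSR axes
Bacterial secretion system	Bacterial secretion system	foraging	synthetic stand-in: representative foraging pathway (resource scavenging); outside the CSR axes
Phosphotransferase system (PTS)	Phosphotransferase system (PTS)	foraging	synthetic stand-in: representative foraging pathway (nutrient sensing/uptake); outside the CSR axes
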