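id	display_name	node_type	fdr	betweenness
CACNA1C	Calcium voltage-gated channel subunit alpha1 C	gene		0.338153
GRIA1	Glutamate ionotropic receptor AMPA-type subunit 1	gene		0.1574122
DRD2	Dopamine receptor D2	gene		0.1136524
NOS1	Nitric oxide synthase 1	gene		0.0903783
SLC18A1	Solute carrier family 18 member A1	gene		0.06612326
HTR2A	5-Hydroxytryptamine receptor 2A	gene		0.0660831
DRD1	Dopamine receptor D1	gene		0.0500920
GRIK2	Glutamate ionotropic receptor kainate-type subunit 2	gene		0.0481045
DRD5	Dopamine receptor D5	gene		0.0458659
HTR1A	5-Hydroxytryptamine receptor 1A	gene		0.0443705
GRIN2B	Glutamate ionotropic receptor NMDA-type subunit 2B	gene		0.036738
SLC6A4	Solute carrier family 6 member 4	gene		0.020317
GRIK3	Glutamate ionotropic receptor kainate-type subunit 3	gene		0.038491
DRD3	Dopamine receptor D3	gene		0.017168
CNR1	Cannabinoid receptor 1	gene		0.007217
ADRA1A	Adrenoceptor alpha 1A	gene		0.006255
BDNF	Brain-derived neurotrophic factor	gene		0.005617
TPH2	Tryptophan hydroxylase 2	gene		0.0045508
DRD4	Dopamine receptor D4	gene		0.004232
GAD1	Glutamate decarboxylase 1	gene		0.003155
GABRA1	Gamma-aminobutyric acid type A receptor alpha1 subunit	gene		0.001786
NTRK2	Neurotrophic receptor tyrosine kinase 2	gene		0.001023
ACE	Angiotensin I converting enzyme	gene		0
ATXN1	Ataxin 1	gene		0
CHRNA7	Cholinergic receptor nicotinic alpha 7 subunit	gene		0
CRHR2	Corticotropin-releasing hormone receptor 2	gene		0
DBH	Dopamine beta-hydroxylase	gene		0
EFNA5	Ephrin A5	gene		0
GAD2	Glutamic acid decarboxylase 2	gene		0
GRIN2A	Glutamate ionotropic receptor NMDA-type subunit 2A	gene		0
HTR2C	5-Hydroxytryptamine receptor 2C	gene		0
HTR3A	5-Hydroxytryptamine receptor 3A	gene		0
OLFM1	Olfactomedin 1	gene		0
TNF	Tumor necrosis factor	gene		0
hsa04728	Dopaminergic synapse	pathway	3.86E-08	0.13604918
hsa04024	cAMP signaling pathway	pathway	1.19E-06	0.12989786
hsa04726	Serotonergic synapse	pathway	0.000112	0.0838125
hsa04020	Calcium signaling pathway	pathway	0.000979	0.07812904
hsa04724	Glutamatergic synapse	pathway	0.001158	0.04450784
hsa04727	GABAergic synapse	pathway	0.005543	0.03118593
hsa04723	Retrograde endocannabinoid signaling	pathway	0.00753	0.04801305
GO:0035240	Dopamine binding	molecular_function	3.59E-10	0.011851
GO:0001588	Dopamine neurotransmitter receptor activity, coupled via Gs	molecular_function	9.72E-09	0.0047987
GO:0005234	Extracellular-glutamate-gated ion channel activity	molecular_function	2.06E-06	0
GO:0008227	G-protein-coupled amine receptor activity	molecular_function	0.000142	0.00705387
GO:0016597	Amino acid binding	molecular_function	0.000211	0.02687112
GO:0015277	Kainate-selective glutamate receptor activity	molecular_function	0.00151	0
GO:0008504	Monoamine transmembrane transporter activity	molecular_function	0.004829	0.00237254
GO:0051378	Serotonin binding	molecular_function	0.004829	5.53E-04
GO:0008519	Ammonium transmembrane transporter activity	molecular_function	0.028746	0.00237254
GO:0099589	Serotonin receptor activity	molecular_function	0.028746	5.53E-04
GO:0030425	Dendrite	cellular_component	0.000151	0.07980464
GO:0033267	Axon part	cellular_component	0.000215	0.03089599
GO:0014069	Postsynaptic density	cellular_component	0.000243	0.05051219
GO:0008328	Ionotropic glutamate receptor complex	cellular_component	0.001148	0.0055914
GO:0045121	Membrane raft	cellular_component	0.001158	0.05504978
GO:0034703	Cation channel complex	cellular_component	0.003335	0.02751275
GO:0043204	Perikaryon	cellular_component	0.01023	0.00847745
GO:0008021	Synaptic vesicle	cellular_component	0.013692	0.01103456
CORTEX	Cortex	brain_region	0.008	0.22937063
STRIATUM	Striatum	brain_region	0.008	0.1299988
HIPPOCAMPUS	Hippocampus	brain_region	0.008	0.07421981
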