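concept_id	type	preferred_label	synonym
	DISEASE	Alzheimer's Disease	Alzheimer disease
	DISEASE	Alzheimer's Disease	Alzheimers disease
	DISEASE	Alzheimer's Disease	AD
	DISEASE	Early Onset Alzheimer's Disease	early-onset Alzheimer's disease
	DISEASE	Early Onset Familial Alzheimer's Disease	early onset familial Alzheimer's disease
	DISEASE	Familial Alzheimer's Disease	familial AD
	DISEASE	Incipient Alzheimer's Disease	
	DISEASE	Late Onset Alzheimer's Disease	late-onset Alzheimer's disease
	DISEASE	Late Onset Sporadic Alzheimer's Disease	
	DISEASE	Mid-Stage Alzheimer's Disease	
	DISEASE	Mild-to-Moderate Alzheimer's Disease	
	DISEASE	Moderate Alzheimer's Disease	
	DISEASE	Moderate-to-Severe Alzheimer's Disease	
	DISEASE	Sporadic Alzheimer's Disease	
	DISEASE	Severe Alzheimer's Disease	
	PATHOLOGICAL_OBSERVATION	Acute-Phase Reaction	acute phase response
	PATHOLOGICAL_OBSERVATION	Amyloid Deposition	abnormal deposition of amyloid plaques
	PATHOLOGICAL_OBSERVATION	Amyloid Deposition	amyloid infiltration
	PATHOLOGICAL_OBSERVATION	Amyloid Deposition	amyloid deposits
	PATHOLOGICAL_OBSERVATION	Amyloid Deposition	amyloid protein deposition
	PATHOLOGICAL_OBSERVATION	Amyloid Fibril Formation	amyloid formation
	PATHOLOGICAL_OBSERVATION	Amyloid Fibril Formation	amyloid fibrillogenesis
	PATHOLOGICAL_OBSERVATION	Amyloidosis	
	PATHOLOGICAL_OBSERVATION	Asymmetric Cortical Atrophy	
	PATHOLOGICAL_OBSERVATION	Blood Brain Barrier Dysfunction	blood-brain barrier breakdown
	PATHOLOGICAL_OBSERVATION	Central Nervous System Inflammation	CNS inflammation
	PATHOLOGICAL_OBSERVATION	Cerebral Atrophy	brain atrophy
	PATHOLOGICAL_OBSERVATION	Cholinergic Dysfunction	
	PATHOLOGICAL_OBSERVATION	Corpus Callosum Atrophy	
	PATHOLOGICAL_OBSERVATION	Dystrophic Neuronal Growth	
	PATHOLOGICAL_OBSERVATION	Glial Inflammation	
	PATHOLOGICAL_OBSERVATION	Gliosis	
	PATHOLOGICAL_OBSERVATION	Glucose Hypometabolism	
	PATHOLOGICAL_OBSERVATION	Granulovacuolar Degeneration	
	PATHOLOGICAL_OBSERVATION	Hippocampal Neurodegeneration	
	PATHOLOGICAL_OBSERVATION	Inflammation	
	PATHOLOGICAL_OBSERVATION	Locus Coeruleus Neuronal Loss	
	PATHOLOGICAL_OBSERVATION	Mitochondrial Failure	mitochondrial dysfunction
	PATHOLOGICAL_OBSERVATION	Nerve Degeneration	
	PATHOLOGICAL_OBSERVATION	Neuritic Plaque Formation	neuritic plaques
	PATHOLOGICAL_OBSERVATION	Neurofibrillary Degeneration	
	PATHOLOGICAL_OBSERVATION	Neurofibrillary Lesion	
	PATHOLOGICAL_OBSERVATION	Neurofibrillary Tangle Formation	neurofibrillary tangles
	PATHOLOGICAL_OBSERVATION	Neuroinflammation	
	PATHOLOGICAL_OBSERVATION	Neuronal Degeneration	neuronal neurodegeneration
	PATHOLOGICAL_OBSERVATION	Neuronal Degeneration	degeneration of neurons
	PATHOLOGICAL_OBSERVATION	Neuronal Dysfunction	
	PATHOLOGICAL_OBSERVATION	Neuronal Dystrophy	
	PATHOLOGICAL_OBSERVATION	Neuronal Inclusion Bodies	
	PATHOLOGICAL_OBSERVATION	Neuronal Lesion	
	PATHOLOGICAL_OBSERVATION	Neuronal Loss	loss of neurons
	PATHOLOGICAL_OBSERVATION	Neuronal Necrosis	
	PATHOLOGICAL_OBSERVATION	Neuronal Shrinkage	
	PATHOLOGICAL_OBSERVATION	Occipital Atrophy	
	PATHOLOGICAL_OBSERVATION	Oxidative Damage	
	PATHOLOGICAL_OBSERVATION	Oxidative Stress	
	PATHOLOGICAL_OBSERVATION	Perivascular Amyloidosis	
	PATHOLOGICAL_OBSERVATION	Synapse Dysfunction	synaptic dysfunction
	PATHOLOGICAL_OBSERVATION	Synaptic Degeneration	
	PATHOLOGICAL_OBSERVATION	Synaptic Loss	loss of synapses
	PATHOLOGICAL_OBSERVATION	Synapse Enlargement	
	PATHOLOGICAL_OBSERVATION	Tau Deposition	deposition of tau
	PATHOLOGICAL_OBSERVATION	Tau Phosphorylation	phosphorylation of tau
	PATHOLOGICAL_OBSERVATION	Tau Phosphorylation	tau hyperphosphorylation
	PATHOLOGICAL_OBSERVATION	Tau-Mediated Cytotoxicity	
	ANATOMICAL_STRUCTURE	Amygdala	
	ANATOMICAL_STRUCTURE	Anterior Thalamic Nucleus	
	ANATOMICAL_STRUCTURE	Basal Nucleus of Meynert	nucleus basalis of Meynert
	ANATOMICAL_STRUCTURE	CA1 region	CA1
	ANATOMICAL_STRUCTURE	CA2 region	CA2
	ANATOMICAL_STRUCTURE	CA3 region	CA3
	ANATOMICAL_STRUCTURE	Cholinergic Neuron	cholinergic neurons
	ANATOMICAL_STRUCTURE	Diagonal Band of Broca	
	ANATOMICAL_STRUCTURE	Entorhinal Cortex	
	ANATOMICAL_STRUCTURE	Frontal Lobe	frontal cortex
	ANATOMICAL_STRUCTURE	Hippocampus	hippocampal formation
	ANATOMICAL_STRUCTURE	Inferior Temporal Gyrus	
	ANATOMICAL_STRUCTURE	Left Thalamus	
	ANATOMICAL_STRUCTURE	Locus Coeruleus	
	ANATOMICAL_STRUCTURE	Medial Temporal Cortex	
	ANATOMICAL_STRUCTURE	Parahippocampal Gyrus	
	ANATOMICAL_STRUCTURE	Parietal Lobe	parietal cortex
	ANATOMICAL_STRUCTURE	Prefrontal Cortex	
	ANATOMICAL_STRUCTURE	Septal Nucleus	
	ANATOMICAL_STRUCTURE	Subiculum	
	ANATOMICAL_STRUCTURE	Substantia Innominata	
	ANATOMICAL_STRUCTURE	Superior Temporal Gyrus	
	ANATOMICAL_STRUCTURE	Synapse	synapses
	ANATOMICAL_STRUCTURE	Temporal Isocortex	
	ANATOMICAL_STRUCTURE	Temporal Lobe	temporal cortex
	ANATOMICAL_STRUCTURE	Thalamus	
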