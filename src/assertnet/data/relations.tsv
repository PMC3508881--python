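relation_class	preferred_relation	surface_form
PATHOLOGY_LINK	AFFECTS	affects
PATHOLOGY_LINK	CAUSES	causes
PATHOLOGY_LINK	HAS FEATURE	has feature
PATHOLOGY_LINK	HAS FEATURE	is characterized by
PATHOLOGY_LINK	LEADS TO	leads to
PATHOLOGY_LINK	RESULTS IN	results in
PATHOLOGY_LINK	IS INVOLVED IN	is involved in
PATHOLOGY_LINK	IS INVOLVED IN	contributes to
PATHOLOGY_LINK	IS INVOLVED IN	plays a role in
EXPRESSION	IS EXPRESSED IN	is expressed in
EXPRESSION	IS EXPRESSED IN	is present in
EXPRESSION	IS EXPRESSED IN	is detected in
EXPRESSION	IS LOCATED IN	is located in
EXPRESSION	EXPRESSES	expresses
EXPRESSION	HAS CONSTITUENT	has constituent
EXPRESSION	HAS CONSTITUENT	contains
EXPRESSION	IS LOCATION OF	is location of
EXPRESSION	IS SITE OF ALTERATION OF	is site of alteration of
UPREGULATION	IS INCREASED IN	is increased in
UPREGULATION	IS INCREASED IN	is elevated in
UPREGULATION	IS INCREASED IN	is raised in
UPREGULATION	IS HIGHER IN	is higher in
UPREGULATION	IS UPREGULATED IN	is upregulated in
UPREGULATION	IS UPREGULATED IN	is up-regulated in
UPREGULATION	HAS UPREGULATED	has upregulated
DISEASE_LINK	IS ASSOCIATED WITH	is associated with
DISEASE_LINK	IS ASSOCIATED WITH	is linked to
DISEASE_LINK	IS RISK FACTOR FOR	is risk factor for
DISEASE_LINK	IS RISK FACTOR FOR	is a risk factor for
DISEASE_LINK	IS ALTERED IN	is altered in
DISEASE_LINK	IS AFFECTED IN	is affected in
DISEASE_LINK	IS BIOMARKER FOR	is biomarker for
DISEASE_LINK	IS BIOMARKER FOR	is a biomarker for
PATHWAY_MEMBERSHIP	IS COMPONENT OF	is component of
PATHWAY_MEMBERSHIP	IS COMPONENT OF	is a component of
PATHWAY_MEMBERSHIP	PARTICIPATES IN	participates in
PATHOLOGY_LINK	HAS FEATURE	are characterized by
PATHOLOGY_LINK	IS INVOLVED IN	are involved in
EXPRESSION	IS EXPRESSED IN	are expressed in
EXPRESSION	IS EXPRESSED IN	are present in
EXPRESSION	IS EXPRESSED IN	are detected in
EXPRESSION	IS LOCATED IN	are located in
EXPRESSION	IS LOCATION OF	are location of
EXPRESSION	IS SITE OF ALTERATION OF	are site of alteration of
UPREGULATION	IS INCREASED IN	are increased in
UPREGULATION	IS INCREASED IN	are elevated in
UPREGULATION	IS INCREASED IN	are raised in
UPREGULATION	IS HIGHER IN	are higher in
UPREGULATION	IS UPREGULATED IN	are upregulated in
UPREGULATION	IS UPREGULATED IN	are up-regulated in
DISEASE_LINK	IS ASSOCIATED WITH	are associated with
DISEASE_LINK	IS ASSOCIATED WITH	are linked to
DISEASE_LINK	IS RISK FACTOR FOR	are risk factor for
DISEASE_LINK	IS RISK FACTOR FOR	are a risk factor for
DISEASE_LINK	IS ALTERED IN	are altered in
DISEASE_LINK	IS AFFECTED IN	are affected in
DISEASE_LINK	IS BIOMARKER FOR	are biomarker for
DISEASE_LINK	IS BIOMARKER FOR	are a biomarker for
PATHWAY_MEMBERSHIP	IS COMPONENT OF	are component of
PATHWAY_MEMBERSHIP	IS COMPONENT OF	are a component of
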