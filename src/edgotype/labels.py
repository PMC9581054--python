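"""Canonical string labels used across the pipeline."""

# Edgotypes: the interactome perturbation pattern of a mutation.
QUASI_WILDTYPE = "quasi-wild-type"
EDGETIC = "edgetic"
QUASI_NULL = "quasi-null"
EDGOTYPES = (QUASI_WILDTYPE, EDGETIC, QUASI_NULL)

# Structural location classes.
INTERFACIAL = "interfacial"
BURIED = "buried"
EXPOSED = "exposed"
LOCATIONS = (INTERFACIAL, BURIED, EXPOSED)

# Fitness classes for new missense mutations.
NEUTRAL = "neutral"
MILD = "mildly-deleterious"
STRONG = "strongly-detrimental"
FITNESS_CLASSES = (NEUTRAL, MILD, STRONG)

# Phenotype classes of the observed mutation sets.
NONPATHOGENIC = "nonpathogenic"
PATHOGENIC = "pathogenic"
PHENOTYPE_CLASSES = (NONPATHOGENIC, PATHOGENIC)

# Assumptions about the edgotype distribution of strongly detrimental
# mutations: "I" = all quasi-null; "II" = distributed like mildly
# deleterious mutations.
ASSUMPTION_I = "I"
ASSUMPTION_II = "II"
ASSUMPTIONS = (ASSUMPTION_I, ASSUMPTION_II)
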