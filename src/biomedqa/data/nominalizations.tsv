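# verb <TAB> nominal(s) — NomLEX-style lexicon, user-extensible
induce	induction
treat	treatment
diagnose	diagnosis
inhibit	inhibition
activate	activation
regulate	regulation
express	expression
associate	association
relate	relation	relationship
cause	causation
mutate	mutation
prevent	prevention
suppress	suppression
mediate	mediation
transcribe	transcription
translate	translation
replicate	replication
infect	infection
develop	development
respond	response
resist	resistance
recommend	recommendation
stimulate	stimulation
interact	interaction
bind	binding
signal	signaling
degrade	degradation
metabolize	metabolism
accumulate	accumulation
differentiate	differentiation
proliferate	proliferation
apoptose	apoptosis
secrete	secretion
absorb	absorption
excrete	excretion
oxidize	oxidation
reduce	reduction
phosphorylate	phosphorylation
methylate	methylation
produce	production
form	formation
contribute	contribution
report	report
observe	observation
measure	measurement
evaluate	evaluation
compare	comparison
analyze	analysis
detect	detection
identify	identification
characterize	characterization
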