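# Filler vocabulary for synthetic gene-set names: lemma-stable English
# words (no plural forms), none of which are stop words or default
# exclusions, so tokenisation leaves them unchanged.
membrane
kinase
receptor
binding
transport
nuclear
response
growth
adhesion
migration
repair
damage
transcription
translation
folding
oxidative
vesicle
lysosome
golgi
cytoskeleton
junction
polarity
division
checkpoint
replication
elongation
initiation
termination
export
import
assembly
remodeling
activation
inhibition
maintenance
differentiation
secretion
localization
signal
turnover
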