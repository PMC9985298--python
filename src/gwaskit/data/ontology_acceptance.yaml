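# Default per-ontology acceptance (community-trust) scores, consumed as an
# external input by the annotation scorer. Values are configuration, not
# computed: replace or extend this map to reflect a different trust policy.
EFO: 0.32
NCIT: 0.86
HP: 0.31
MONDO: 0.26
DOID: 0.39
MP: 0.28
SYMP: 0.25
OMIT: 0.18
MAXO: 0.13
NBO: 0.19
MPATH: 0.19
SNOMED: 0.45
ENM: 0.30
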