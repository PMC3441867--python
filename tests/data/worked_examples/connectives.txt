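# Illustrative discourse-connective lexicon (connective<TAB>direction).
# direction says which side of the connective holds the cause span:
#   cause-first  — text before the connective is the cause (e.g. "so")
#   effect-first — the cause follows the connective (e.g. "because")
because	effect-first
so	cause-first
therefore	cause-first
as a result	cause-first
since	effect-first
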