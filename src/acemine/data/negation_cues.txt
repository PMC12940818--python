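# Negation cue lexicon: one cue per line, single- or multi-token.
no
not
without
lack of
fail to
fails to
failed to
does not
did not
do not
cannot
neither
nor
absence of
unable to
never
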