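status,treatment,control
not_abstained,271,289
abstained,80,82
missing,526,510
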