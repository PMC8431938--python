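# Trait tokens ending in "-oma" that are NOT cancer-related and must not
# trigger the cancer-trait exclusion. Lower-case, one per line; editable.
glaucoma
hematoma
haematoma
xanthoma
coloboma
granuloma
atheroma
tuberculoma
mycetoma
hygroma
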