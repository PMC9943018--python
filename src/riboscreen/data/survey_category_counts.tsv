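# Absolute frequencies of the ten functional groups among genes regulated by
# antisense-acting riboswitches in the representative-genome screen.
# Columns: category, count.
category	count
interconversion	116
cofactor	25
transporter	69
signaling	12
tf	70
transposase	54
pseudogene	50
uncharacterized	57
hypothetical	274
other	78
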