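label	description
Economic	The interaction has financial impact for human society
Economic (crop pest)	The interaction is damaging to food crops
Economic (timber pest)	The interaction is damaging to timber
Economic (pest control)	The interaction helps to control a pest species
Medical	The interaction has medical important consequences on humans
Veterinary	The interaction has medical important consequences on animals
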