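label	description
Native	The organism either evolved in this region or arrived by non-anthropogenic means.
Naturalised	The organism reproduces naturally and forms part of the local ecology.
Introduced	The organism arrived in the region via an anthropogenic mechanism or mechanisms.
Invasive	The organism is having a deleterious impact on another organism, multiple organisms or the ecosystem as a whole.
Captivity	The organism is kept in captivity.
Managed	The organism maintains its presence through intentional cultivation or husbandry.
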