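label	description
Interaction recorded in the wild	
Interaction recorded in captivity	Used when the status of the specimens is uncertain
Interaction recorded in captivity from wild caught specimens	
Interaction recorded in captivity from captive bred specimens	
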