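label	uri	inverse_label	inverse_uri	parent_label
interacts with	http://purl.obolibrary.org/obo/RO_0002434	interacts with	http://purl.obolibrary.org/obo/RO_0002434	
eats	http://purl.obolibrary.org/obo/RO_0002470	eaten by	http://purl.obolibrary.org/obo/RO_0002471	interacts with
eaten by	http://purl.obolibrary.org/obo/RO_0002471	eats	http://purl.obolibrary.org/obo/RO_0002470	interacts with
preys on	http://purl.obolibrary.org/obo/RO_0002439	preyed on by	http://purl.obolibrary.org/obo/RO_0002458	interacts with
preyed on by	http://purl.obolibrary.org/obo/RO_0002458	preys on	http://purl.obolibrary.org/obo/RO_0002439	interacts with
pollinates	http://purl.obolibrary.org/obo/RO_0002455	pollinated by	http://purl.obolibrary.org/obo/RO_0002456	interacts with
pollinated by	http://purl.obolibrary.org/obo/RO_0002456	pollinates	http://purl.obolibrary.org/obo/RO_0002455	interacts with
parasite of	http://purl.obolibrary.org/obo/RO_0002444	parasitized by	http://purl.obolibrary.org/obo/RO_0002445	interacts with
parasitized by	http://purl.obolibrary.org/obo/RO_0002445	parasite of	http://purl.obolibrary.org/obo/RO_0002444	interacts with
ectoparasite of	http://purl.obolibrary.org/obo/RO_0002632	ectoparasitized by	http://purl.obolibrary.org/obo/RO_0002633	parasite of
ectoparasitized by	http://purl.obolibrary.org/obo/RO_0002633	ectoparasite of	http://purl.obolibrary.org/obo/RO_0002632	parasitized by
endoparasite of	http://purl.obolibrary.org/obo/RO_0002634	endoparasitized by	http://purl.obolibrary.org/obo/RO_0002635	parasite of
endoparasitized by	http://purl.obolibrary.org/obo/RO_0002635	endoparasite of	http://purl.obolibrary.org/obo/RO_0002634	parasitized by
host of	http://purl.obolibrary.org/obo/RO_0002453	has host	http://purl.obolibrary.org/obo/RO_0002454	interacts with
has host	http://purl.obolibrary.org/obo/RO_0002454	host of	http://purl.obolibrary.org/obo/RO_0002453	interacts with
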