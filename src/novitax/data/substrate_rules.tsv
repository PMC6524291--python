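pattern	substrate	weight
GH13:pullulanase	pullulan	1.0
GH13:amylase	starch	1.0
GH10|GH11 & GH43|GH3:beta-xylosidase	xylan	1.0
GH53	arabinogalactan	1.0
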