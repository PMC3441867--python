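{"id":"e3","cause":[["I","other"],["broke_up","verb"],["with","other"],["my","other"],["boyfriend","noun"]],"effect":[["Life","noun"],["now","other"],["is","other"],["meaningless","verb"],["to","other"],["me","other"]],"label":"causality"}
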