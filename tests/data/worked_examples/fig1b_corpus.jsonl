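{"id":"p1","cause":[["I","other"],["broke_up","verb"],["with","other"],["my","other"],["boyfriend","noun"]],"effect":[["life","noun"],["now","other"],["is","other"],["meaningless","verb"]],"label":"causality"}
{"id":"p2","cause":[["she","other"],["broke_up","verb"],["with","other"],["her","other"],["boyfriend","noun"],["yesterday","noun"]],"effect":[["her","other"],["life","noun"],["feels","verb"],["meaningless","verb"]],"label":"causality"}
{"id":"p3","cause":[["we","other"],["broke_up","verb"],["boyfriend","noun"],["moved","verb"],["away","other"]],"effect":[["my","other"],["life","noun"],["seems","verb"],["meaningless","verb"],["now","other"]],"label":"causality"}
{"id":"p4","cause":[["I","other"],["failed","verb"],["the","other"],["exam","noun"]],"effect":[["I","other"],["felt","verb"],["upset","verb"]],"label":"causality"}
{"id":"p5","cause":[["he","other"],["failed","verb"],["his","other"],["exam","noun"],["again","other"]],"effect":[["he","other"],["felt","verb"],["very","other"],["upset","verb"]],"label":"causality"}
{"id":"p6","cause":[["the","other"],["weather","noun"],["changed","verb"]],"effect":[["we","other"],["stayed","verb"],["home","noun"]],"label":"causality"}
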