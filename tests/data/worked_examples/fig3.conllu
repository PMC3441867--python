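# sent_id = e1/cause
1	My	my	OTHER	_	_	2	poss	_	_
2	boss	boss	NOUN	_	_	3	nsubj	_	_
3	cut	cut	VERB	_	_	0	root	_	_
4	my	my	OTHER	_	_	5	poss	_	_
5	salary	salary	NOUN	_	_	3	obj	_	_
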