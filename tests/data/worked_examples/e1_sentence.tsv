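e1	I/other couldn't/other sleep/verb for/other several/other days/noun because/other my/other boss/noun cut/verb my/other salary/noun
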