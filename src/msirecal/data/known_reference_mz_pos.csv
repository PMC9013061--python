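mz
309.2036
441.2975
457.2715
469.3288
621.4855
621.4878
649.5168
649.5191
713.4518
723.4935
739.4675
782.5670
798.5408
798.5410
820.5253
824.5566
826.5721
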