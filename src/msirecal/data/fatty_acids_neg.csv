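name,formula,neutral_mass,class
palmitoleic acid,C16H30O2,254.22458,fatty acid
palmitic acid,C16H32O2,256.24023,fatty acid
margaric acid,C17H34O2,270.25588,fatty acid
linoleic acid,C18H32O2,280.24023,fatty acid
oleic acid,C18H34O2,282.25588,fatty acid
stearic acid,C18H36O2,284.27153,fatty acid
arachidonic acid,C20H32O2,304.24023,fatty acid
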