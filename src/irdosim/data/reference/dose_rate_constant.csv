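# dose rate constant (cGy/h/U) comparison fixture
source,study,value,uncertainty
GammaMed Plus,this_mc,1.115,0.003
GammaMed Plus,ballester_geant,1.118,0.003
GammaMed Plus,taylor_brachydose,1.115,0.003
MicroSelectron,williamson_mc,1.115,0.005
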