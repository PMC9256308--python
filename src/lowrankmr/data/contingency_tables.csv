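sequence,tp,fp,fn,tn
plain,118,4,19,9
DWI,126,3,11,10
DCE,133,1,4,12
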