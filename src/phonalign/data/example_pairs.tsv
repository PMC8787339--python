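id	stimulus	response
1	fun	thin
2	these are your books	we live on the earth
3	key	key
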