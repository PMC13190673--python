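rank	from_name	to_name	source
species	Ceratium muelleri	Tripos muelleri	example (synthetic)
species	Tabellaria fenestra	Tabellaria fenestrata	example (synthetic)
genus	Ceratium	Tripos	example (synthetic)
genus	Emiliania	Gephyrocapsa	example (synthetic)
class	Prymnesiophyceae	Coccolithophyceae	example (synthetic)
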