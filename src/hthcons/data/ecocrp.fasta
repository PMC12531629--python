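>EcoCRP E. coli cyclic AMP receptor protein, mature chain (209 aa)
VLGKPQTDPTLEWFLSHCHIHKYPSKSTLIHQGEKAETLYYIVKGSVAVLIKDEEGKEMI
LSYLNQGDFIGELGLFEEGQERSAWVRAKTACEVAEISYKKFRQLIQVNPDILMRLSAQM
ARRLQVTSEKVGNLAFLDVTGRIAQTLLNLAKQPDAMTHPDGMQIKITRQEIGQIVGCSR
ETVGRILKMLEDQNLISAHGKTIVVYGTR
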