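name,formula,monoisotopic_mass
levodopa,C9H11NO4,197.068808
entacapone,C14H15N3O5,305.101172
dopamine,C8H11NO2,153.078979
dihydroxyphenylacetic acid,C8H8O4,168.042259
homovanillic acid,C9H10O4,182.057909
3-O-methyldopa,C10H13NO4,211.084458
S-adenosyl-L-methionine,C15H22N6O5S,398.137236
norepinephrine,C8H11NO3,169.073893
epinephrine,C9H13NO3,183.089543
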