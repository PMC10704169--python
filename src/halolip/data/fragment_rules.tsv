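applies_to	adduct	kind	value	label	intensity
# Default class-level fragmentation rules for archaeal ether lipids.
# These are reconstructions from generic ether-lipid CID behaviour, not
# measured spectra; override with your own table for instrument-specific work.
phospholipid	*	neutral_loss	HEAD	head group loss	80
glycolipid	*	neutral_loss	HEAD	head group loss	80
cardiolipin	*	neutral_loss	HEAD	head group loss	60
phospholipid	*	neutral_loss	HEAD_H2O	head group + water loss	40
glycolipid	*	neutral_loss	HEAD_H2O	head group + water loss	40
phospholipid	*	diagnostic_ion	DIAG_HEAD	protonated head group	30
glycolipid	*	diagnostic_ion	DIAG_HEAD	protonated head group	30
phospholipid	*	diagnostic_ion	DIAG_HEAD_H2O	dehydrated head group ion	20
glycolipid	*	neutral_loss	C6H10O5	hexose loss	60
cardiolipin	*	neutral_loss	C6H10O5	hexose loss	40
S-MGD	*	neutral_loss	SO3	sulfate loss	50
S-DGD	*	neutral_loss	SO3	sulfate loss	50
2S-DGD	*	neutral_loss	SO3	sulfate loss	50
S-Gly-AHH	*	neutral_loss	SO3	sulfate loss	50
2S-Gly-AHH	*	neutral_loss	SO3	sulfate loss	50
S-DGD-PA	*	neutral_loss	SO3	sulfate loss	50
*	[M+H]+	neutral_loss	H2O	water loss	30
*	[M+NH4]+	neutral_loss	H2O	water loss	30
phospholipid	[M+H]+	neutral_loss	CHAIN	phytanyl chain loss	35
phospholipid	[M+NH4]+	neutral_loss	CHAIN	phytanyl chain loss	35
glycolipid	[M+H]+	neutral_loss	CHAIN	phytanyl chain loss	35
glycolipid	[M+NH4]+	neutral_loss	CHAIN	phytanyl chain loss	35
core	[M+H]+	neutral_loss	CHAIN	phytanyl chain loss	35
phospholipid	*	neutral_loss	CHAIN_H2O	chain + water loss	25
glycolipid	*	neutral_loss	CHAIN_H2O	chain + water loss	25
core	[M+H]+	neutral_loss	CHAIN_H2O	chain + water loss	25
PI	[M+H]+	diagnostic_ion	mz:261.038	PI head-group ion	40
MK	*	diagnostic_ion	mz:187.0754	methylnaphthoquinone ion	45
*	[M+Na]+	neutral_loss	CHAIN_SEQ	sequential intact unsaturated chain loss	70
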