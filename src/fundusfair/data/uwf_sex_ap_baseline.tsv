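# Per-disease average precision (%) by patient sex for the single-branch
# baseline disease classifier (ResNet-101 backbone), evaluated on the same
# ultra-widefield test split as the two-branch model (38 disease types).
# Transcribed from the published per-disease results table; "-" marks a
# cell with no positive test samples for that sex (AP undefined).
disease	male	female
AH	99.2	99.3
Aneurysms	42.8	79.9
BRVO	100	94.1
Cataract	80.1	80.4
Chorioretinitis	86.7	73.3
Choroidal diseases	77.2	77.7
Coats	94.9	86.5
CRVO	98.3	78.0
FEVR	94.4	75.4
Fibrosis	64.0	56.7
Floaters	92.8	90.6
Fundus neoplasm	92.4	87.9
HM	74.5	82.6
Isolated drusen	80.1	89.6
Isolated vessel tortuosity	76.3	65.8
Laser spots	92.5	94.3
Maculopathy	96.1	88.4
MH	72.6	95.5
Myelinated nerve fiber	68.9	98.9
Normal	96.8	95.0
Optic abnormalities	71.2	62.0
PDR	97.1	97.7
Peripheral retinal degeneration	85.9	94.3
PM	94.4	97.3
Retinal white dots	-	92.1
RP	100	99.8
Silicone oil	98.6	100
Surgery-air	100	100
Surgery-band:buckle	88.7	100
Surgery-medicine	90.0	75
TRD	81.3	81.8
Vasculitis	88.0	98.2
ERM	88.0	93.7
Vitreous opacity	89.9	84.4
Lens dislocation	94.0	100
VKH	97.8	98.5
RD	88.3	89.8
Retinal breaks	78.7	94.7
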