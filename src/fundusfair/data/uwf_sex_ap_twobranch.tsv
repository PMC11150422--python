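# Per-disease average precision (%) by patient sex for the two-branch
# pathology-aware screening model, evaluated on the test split of an
# ultra-widefield fundus dataset covering 38 disease types.
# Transcribed from the published per-disease results table; "-" marks a
# cell with no positive test samples for that sex (AP undefined).
disease	male	female
AH	96.8	100
Aneurysms	44.0	87.8
BRVO	100	98.8
Cataract	89.8	86.8
Chorioretinitis	100	97
Choroidal diseases	82.4	86.9
Coats	97.0	86.9
CRVO	99.2	88.2
FEVR	98.1	100
Fibrosis	75.4	67.2
Floaters	93.2	93.2
Fundus neoplasm	96.2	92.2
HM	89.6	79.9
Isolated drusen	84.3	93.3
Isolated vessel tortuosity	82.2	75.3
Laser spots	94.3	97.0
Maculopathy	98.9	92.2
MH	88.3	96.4
Myelinated nerve fiber	100	100
Normal	96.8	96.2
Optic abnormalities	70.4	70.7
PDR	97.0	97.9
Peripheral retinal degeneration	87.1	93.9
PM	97.7	96.4
Retinal white dots	-	100
RP	100	100
Silicone oil	99.9	100
Surgery-air	100	99.6
Surgery-band:buckle	81.7	100
Surgery-medicine	86.9	58.3
TRD	80.0	83.2
Vasculitis	90.3	100
ERM	88.6	93.6
Vitreous opacity	94.5	87.9
Lens dislocation	100	100
VKH	98.0	99.2
RD	92.3	93.9
Retinal breaks	89.3	96.4
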