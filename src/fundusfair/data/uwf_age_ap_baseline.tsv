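# Per-disease average precision (%) by 10-year patient age bracket for the
# single-branch baseline disease classifier (ResNet-101 backbone) on the
# same ultra-widefield test split (38 disease types). Transcribed from the
# published age-stratified results table; "-" marks a bracket with no
# positive test samples for that disease (AP undefined).
disease	0-10	11-20	21-30	31-40	41-50	51-60	61-70	71-80	81-90
AH	100	-	-	100	-	99.0	100	100	-
Aneurysms	9.6	9.1	100	100	100	41.2	95.6	65.1	100
BRVO	-	-	-	-	100	100	95.9	86.1	100
Cataract	-	50	36.9	65.6	58.3	82.1	85.4	80.8	99
Chorioretinitis	-	-	81.7	75	100	-	-	-	-
Choroidal diseases	100	88.2	87.9	72.1	72.7	79.1	34.4	31	41.7
Coats	100	94.8	100	100	50	10.7	-	-	-
CRVO	-	100	100	100	100	97.6	76.9	100	-
ERM	-	-	55.9	56.7	74.3	96.7	92.9	95.8	100
FEVR	92.3	75.6	100	83.3	-	-	-	-	-
Fibrosis	27.6	33.0	72.4	35.9	66.1	76.4	63.3	67.5	-
Floaters	-	4.2	93.4	71	94.9	92.4	93.2	92.4	91.1
Fundus neoplasm	85.1	75.8	90.9	98.4	98	88.5	69.1	97.6	-
HM	-	100	90.9	86.6	70.1	73.8	83.9	61.0	41.7
Isolated drusen	-	100	100	100	47	81.5	87.8	92.4	94.4
Isolated vessel tortuosity	58.2	87.7	85.1	78.7	58.3	77.3	73.4	69.6	66.7
Laser spots	86.7	66.7	97.1	94.7	93.0	96.4	91.6	95.4	-
Lens dislocation	-	-	-	100	100	100	100	100	-
Maculopathy	-	100	100	100	100	83.5	94.8	95.1	100
MH	100	-	100	100	87.6	86.9	80.0	100	-
Myelinated nerve fiber	100	-	-	-	100	100	75.2	100	-
Normal	99.4	97.2	96.3	92.2	97.3	95.2	92.7	83.3	-
Optic abnormalities	84.6	70.3	68.1	80.5	58.2	72.0	67.4	75.5	58.3
PDR	100	-	92.5	96.7	99.5	99.5	93.2	93.1	-
Peripheral retinal degeneration	62.1	87.5	97.2	97.1	87.8	88.6	91.9	84.9	100
PM	-	100	94.2	85.1	99.2	97.5	97.8	97.7	86.7
RD	61.1	98.7	95.2	96.8	80.6	91.4	89.7	86.7	-
Vitreous opacity	-	11.1	74.5	86.5	88.2	93.6	87.2	88.4	-
Retinal breaks	-	-	52.2	100	76.9	96.9	88.5	82.1	-
Retinal white dots	-	-	83.3	100	-	91.7	-	-	-
RP	100	100	100	100	100	100	100	100	-
Silicone oil	79.2	100	100	100	100	100	100	100	-
Surgery-air	100	-	100	100	100	100	100	100	-
Surgery-band:buckle	-	-	-	100	100	100	90	-	-
Surgery-medicine	95.8	96.4	-	-	57.7	100	100	-	-
TRD	19.6	-	70.6	79.8	92.9	86.2	85.1	-	-
Vasculitis	100	58.7	88.9	89.8	95.0	80.5	100	100	-
VKH	-	100	96.2	100	100	96.0	100	-	-
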