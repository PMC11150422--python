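# Per-disease average precision (%) by 10-year patient age bracket for the
# two-branch pathology-aware screening model on an ultra-widefield fundus
# test split (38 disease types). Transcribed from the published
# age-stratified results table; "-" marks a bracket with no positive test
# samples for that disease (AP undefined).
disease	0-10	11-20	21-30	31-40	41-50	51-60	61-70	71-80	81-90
AH	100	-	-	100	-	94.5	100	100	-
Aneurysms	17.5	10	100	100	100	53.3	100	79.2	100
BRVO	-	-	-	-	100	100	98.9	100	100
Cataract	-	100	73.8	91.1	71.9	84.6	92.8	87.5	100
Chorioretinitis	-	-	100	100	100	-	-	-	-
Choroidal diseases	99.2	96.3	96.7	82.9	76.8	78.7	39.8	69.2	100
Coats	99.4	99	100	100	100	50.4	-	-	-
CRVO	-	100	100	83.3	100	95.8	100	100	-
ERM	-	-	56.3	50.3	67.3	97.2	93	98.2	100
FEVR	100	91.7	100	100	-	-	-	-	-
Fibrosis	35.6	40.8	77.1	49.2	65.5	90.3	73.6	77.4	-
Floaters	-	10	86.3	78.1	95.7	94.8	93.9	94.4	96.0
Fundus neoplasm	94.2	100	93	99.5	99	91	89	100	-
HM	-	96.7	95.0	89.2	66.4	85.4	83.0	74.6	58.3
Isolated drusen	-	100	100	91.7	46	84.3	94.4	94.2	97
Isolated vessel tortuosity	72.9	96.7	89.2	80.2	67.2	80.2	86.2	75.6	100
Laser spots	100	86.3	98.5	99.1	90.9	97.8	95.9	100	-
Lens dislocation	-	-	-	100	100	100	100	100	-
Maculopathy	-	100	83.3	100	97.2	93.1	96.1	97.7	100
MH	100	-	100	100	87.6	97.1	89.7	97.7	-
Myelinated nerve fiber	100	-	-	-	100	100	100	100	-
Normal	97.9	98.5	97.3	95.3	96.9	94.6	92.7	86.7	-
Optic abnormalities	81.6	66.4	69.0	81.1	63.8	66.8	68.0	84.8	58.3
PDR	100	-	98.3	98.1	99.1	99.2	92.4	95.7	-
Peripheral retinal degeneration	83.0	87.8	96.7	94.5	90.9	88.7	92.6	85.5	83.3
PM	-	100	93.8	94.6	98.0	97.8	95.7	98.2	94.4
RD	67.6	100	93.5	99.1	94.8	95.1	96.4	84.4	-
Vitreous opacity	-	25	84.1	89.0	93.8	94.6	95.0	87.7	-
Retinal breaks	-	-	70.6	97.6	97.3	100	88.6	87.7	-
Retinal white dots	-	-	100	100	-	100	-	-	-
RP	100	100	100	100	100	100	100	100	-
Silicone oil	100	100	100	100	100	100	100	100	-
Surgery-air	100	-	100	100	100	97.6	100	100	-
Surgery-band:buckle	-	-	-	100	100	100	88.1	-	-
Surgery-medicine	88.6	87.5	-	-	51.2	100	100	-	-
TRD	15.3	-	88.8	69.3	93.4	84.5	88.1	-	-
Vasculitis	100	81	100	90.4	99.8	75.7	100	100	-
VKH	-	100	96.5	100	100	96.9	98.6	-	-
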