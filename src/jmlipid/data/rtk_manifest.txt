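# Human receptor tyrosine kinase family: 58 receptors, 20 subfamilies.
# One HGNC gene symbol per line; sequences are user-supplied.
EGFR
ERBB2
ERBB3
ERBB4
INSR
IGF1R
INSRR
PDGFRA
PDGFRB
KIT
CSF1R
FLT3
FLT1
KDR
FLT4
FGFR1
FGFR2
FGFR3
FGFR4
PTK7
NTRK1
NTRK2
NTRK3
ROR1
ROR2
MUSK
MET
MST1R
AXL
MERTK
TYRO3
EPHA1
EPHA2
EPHA3
EPHA4
EPHA5
EPHA6
EPHA7
EPHA8
EPHA10
EPHB1
EPHB2
EPHB3
EPHB4
EPHB6
RET
RYK
DDR1
DDR2
ROS1
AATK
LMTK2
LMTK3
LTK
ALK
STYK1
TIE1
TEK
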