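CNCc1ccccc1C(F)(F)F
CCCCC
CNCCc1ccccc1
O=[SH](=O)Cc1ccncc1CCO
COC
CNS(=O)(=O)CC(=O)NCO
C1CCOCC1
O=CNc1cnccn1
CCCC1CCCC1c1ccccc1
FCC1CCCC1
CNCc1cnccc1-c1occc1C1CCCNC1
CCCNCCOC
O=CNCCNS(=O)(=O)CCCl
O=CCCOc1ccoc1
FCSCCC1CCCCC1c1cccnc1
OCCc1sccc1-c1cccs1
COCC(F)(F)F
O=CCCCCC1CCCCC1
c1cc(-c2occc2C2CCCNC2)ccn1
O=CCCCS
OCCCCCC1CCCCC1
c1ccsc1
COS(C)(=O)=O
O=S(=O)(CCO)c1ccccc1-c1ccco1
CC(=O)C(C)CC1CCCCC1
O=COC1CCCC1
CNC1CCNCC1CCO
c1cnccn1
CCS
CCCCCl
CC(COCBr)Cc1cccs1
NC=O
O=CNCOCC1CCOCC1
O=[SH](=O)CCCl
C1CCCC1
CNCCSc1cnccn1
C=CCO
COCCN
c1ccncc1
CNCC[SH](=O)=O
NCCC=O
C1CCNCC1
C=CCOCC1CCNCC1
CCCC(C)C
NCCNCSCCc1ccccc1
CCC
O=CO
CCSCOC
CCCCSc1ccsc1-c1ccccc1
CNCCCNC(=O)C[SH](=O)=O
c1ccc(C2CCCCC2c2ccco2)cc1
CC=O
CCCc1occc1CC
COCC(C)=O
c1ccccc1
c1ccoc1
CCCCS(=O)(=O)C1CCCC1
CCCCO
C=COCCc1sccc1CC
CNCOC(F)(F)F
CCOC(=O)NC(=O)OC1CCNCC1
FC(F)(F)c1ccccc1
C1CCCCC1
CNCC1CCCNC1
CNCCCNCO
CCCC1CCCC1
C=CNCC
CCCCOc1ccoc1
O=CCc1ccoc1
ClCc1ccccc1-c1sccc1-c1cccs1
CC(=O)CCCOCCC(C)C
CNc1ccncc1
CNC
CCCCNCF
COCc1ccccc1
CNc1ccccc1CCO
CNCc1ccncc1
O=CCCO
O=C(NC1CCOCC1)c1ccccc1
CCCCCCCC(=O)C1CCCCC1
O=C(O)COCC1CCCNC1
O=CCS(=O)(=O)CC(=O)OCCl
CC(C)CCCC(=O)O
CNCc1ccsc1
CCCC(=O)NS(=O)(=O)CCCN
CCCNC1CCCC1
FC(F)F
C=CNC(=O)c1ccccc1C(C)C
O=CCC1CCOCC1COc1ccsc1
NC(=O)c1cnccc1CS(=O)(=O)CC=O
CNCc1occc1-c1cccs1
O=[SH](=O)CCNCc1ccncc1CO
NC(=O)CC(=O)c1ccco1
NC(=O)c1sccc1OC(=O)C[SH](=O)=O
CCOCBr
COC#N
CS(=O)(=O)C1CCCOC1
CCSC1CCOCC1
CCOC1CCCCC1S(C)(=O)=O
C=CNC=O
CS(=O)(=O)C[SH](=O)=O
CCCNCC
CC(C)C(=O)O
CC(CCC=O)c1ccccc1CBr
CCCC1CCCCC1
O=CCC1CCNCC1
C[SH](=O)=O
COC(=O)CC1CCNCC1
CNCCCCC#N
NC(=O)C1CCCNC1
CCCCC=O
C=CC1COCCC1NC(=O)C(C)C
COCCSS(C)(=O)=O
CCCOC(=O)c1cnccc1CNC
O=C(OCCS)c1cccnc1
O=S(=O)(CC1CCOCC1)C1CCCCC1
CC(C)C1CCCCC1c1ccncc1
CCCc1cccs1
COCc1ccncc1COC
COCN
C=COCOC=O
C=COCc1ccccc1
CCNCCCOCN
CCCNC
CNCCCCOCC#N
O=CNCCOc1ccccc1CBr
O=COCO
CNCCCCSC#N
CC(CBr)Cc1ccccc1C1CCCOC1
CCOC(=O)NCO
O=C(O)CS(=O)(=O)c1cnccc1C1CCCCC1
CNCCCC1CCCCC1c1ccoc1
ClCC1CCCOC1
CCCCBr
CC(=O)C[SH](=O)=O
COc1ccncc1
c1csc(CCSc2ccncc2C2CCCCC2)c1
COCC1CCCC1
O=COC(=O)O
CNCC1CCCCC1
COCC1CCCOC1
CCC1CCCCC1
O=C(Nc1ccncc1)C1CCCNC1
NCCc1ccco1
O=CNCOCC(=O)NCO
C=CCCO
SCCc1cccnc1
C=CCF
COC1CCCCC1
CNCC1CCCCC1COC
CCNc1ccsc1
COCC1CCCNC1
FCc1cnccc1SCCC1CCCCC1
CCCCN
CCO
O=CCCCNC(=O)Nc1ccoc1
SCCc1sccc1-c1cnccc1C1CCCC1
c1ccc(CCc2occc2-c2ccco2)cc1
C=CCCSC=C
CNCOC(=O)c1cccs1
c1cc(C2CCCCC2C2CCCNC2)co1
CCSS(=O)(=O)CCOC
C=CC(C)C
C=Cc1cnccn1
NCc1cccs1
C=CCOCC=CC1CCCCC1
COCC1CCOCC1S(=O)(=O)CC1CCCCC1
SCCc1ccccc1
C=Cc1cnccc1C1CCCC1
FCc1ccco1
CCSC1CCNCC1C#N
CCOCC(C)C(=O)Nc1ccncc1
COCc1cnccc1OCc1ccccc1
c1cc(C2CCCOC2)co1
FCc1occc1OCCC1CCCC1
CCNC1CCOCC1CCCC1CCCC1
CC(CN)CC1CCCCC1C1CCCNC1
C=CC1CCCC1
O=CCc1ccncc1
NC(=O)NCCc1occc1C[SH](=O)=O
O=C(O)OC(=O)C1CCCCC1
NCc1ccco1
COCCC(C)C1CCNCC1
NCCC1CCCCC1C1CCCC1
CCCC(C)CNCC
NCCOCc1ccco1
C=CC#N
c1cc(COCOCCC2CCCCC2)co1
O=CNc1ccsc1
O=S(=O)(CC(F)(F)F)C1CCCOC1
CC(=O)c1occc1-c1cccnc1
NC(=O)c1cccnc1
NCc1ccccc1C1CCCCC1OC=O
O=C(O)C1CNCCC1C1CCCC1
CCCC=O
c1csc(-c2ccncc2)c1
ClCC=Cc1cccs1
CNCCCCCO
CS(=O)(=O)CCC1CNCCC1C1CCCNC1
COCC(C)CC1CCCNC1
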