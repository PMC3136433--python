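AGCKNFFWKTFTSC
AHALCLTERQIKSNRRMKWKKEN
CYFQNCPRG
DFDMLRCMLGRVYRPCWQV
EILLPNNYNAYESYKYPGMFIALSK
FITKALGISYGRKKRRQC
FVPIFTHSELQKIREKERNKGQ
GRKKRRQPPQC
GWTLNSAGYLLGKFLPLILRKIVTAL
GWTLNSAGYLLGKINLKAPAALAKKIL
GWTLNSAGYLLGPHAI
GWTNLSAGYLLGPPPGFSPFR
HDEFERHAEGTFTSDVSSYLEGQAAKEFIAWLVKGR
IAARIKLRSRQHIKLRHL
ILRRRIRKQAHAHSK
KIWFQNRRMK
KKKQYTSIHHGVVEVD
KKLSECLKRIGDELDS
KLALKALKAALKLA
KLALKLALKALKAA
LLGKINLKALAALAKKIL
LLKTTALLKTTALLKTTA
LLKTTELLKTTELLKTTE
LNSAGYLLGKALAALAKKIL
LNSAGYLLGKLKALAALAK
LRKKKKKH
PVVHLTLRQAGDDFSR
QNLGNQWAVGHLM
RPPGFSPFR
RQIKIFFQNRRMKFKK
RQIKIWFQNRRM
RQIKIWFQNRRMKWK
TERQIKIWFQNRRMK
WSYGLRPG
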