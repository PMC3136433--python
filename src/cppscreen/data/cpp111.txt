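AAVALLPAVLLALLAKNNLKDCGLF
AAVALLPAVLLALLAKNNLKECGLY
AAVALLPAVLLALLAPVQRKQKLMP
AAVALLPAVLLALLAVTDQLGEDFFAVDLEAFLQEFGLLPEKE
AAVLLPVLLAAP
AGYLLGKINLKALAALAKKIL
AGYLLGKLKALAALAKKIL
AHALCLTERQIKIWFQNRRMKWKKEN
AHALCPPERQIKIWFQNRRMKWKKEN
ALWKTLLKKVLKA
AYALCLTERQIKIWFANRRMKWKKEN
CGPGSDDEAAADAQHAAPPKKKRKVGY
CNGRC
CNGRCG
CNGRCGGKKLKLLKLL
CNGRCGGKLAKLAKLAKLAK
CNGRCGGLVTT
GAARVTSWLGRQLRIAGKRLEGRSK
GALFLGFLGAAGSTMGAWSQPKSKRKV
GGRQIKIWFQNRRMKWKK
GIGKFLHSAKKWGKAFVGQIMNC
GLAFLGFLGAAGSTMGAWSQPKSKRKV
GRKKRRQ
GRKKRRQRRPPQC
GRKKRRQRRRC
GRKKRRQRRRPPC
GRKKRRQRRRPQ
GRQLRIAGKRLEGRSK
GWTLNPAGYLLGKINLKALAALAKKIL
GWTLNPPGYLLGKINLKALAALAKKIL
GWTLNSAGYLLGKINLKALAALAKKIL
GWTLNSAGYLLGKINLKALAALAKKLL
GWTLNSAGYLLGKLKALAALAKKIL
GWTLNSKINLKALAALAKKIL
INLKALAALAKKIL
IWFQNRRMKWKK
KALAALLKKWAKLLAALK
KALAKALAKLWKALAKAA
KALKKLLAKWAAAKALL
KCRKKKRRQRRRKKLSECLKRIGDELDS
KCRKKKRRQRRRKKPVVHLTLRQAGDDFSR
KETWWETWWTEWSQPKKKRKV
KETWWETWWTEWSQPKKRKV
KFHTFPQTAIGVGAP
KITLKLAIKAWKLALKAA
KIWFQNRRMKWKK
KLAAALLKKWKKLAAALL
KLALKALKALKAALKLA
KLALKLALKALKAALK
KLALKLALKALQAALQLA
KLALKLALKAWKAALKLA
KLALQLALQALQAALQLA
KMTRAQRRAAARRNRWTAR
KRPAATKKAGQAKKKKL
LGTYTQDFNKFHTFPQTAIGVGAP
LIRLWSHLIHIWFQNRRLKWKKK
LKTLATALTKLAKTLTTL
LKTLTETLKELTKTLTEL
LLGDFFRKSKEKIGKEFKRIVQRIKDFLRNLVPRTESC
LLIILRARIRKQAHAHSK
LLIILRRPIRKQAHAHSK
LLIILRRRIRKQAHAHSA
LLIILRRRIRKQAHAHSK
LNSAGYLLGKINLKALAALAKKIL
LNSAGYLLGKLKALAALAKIL
MANLGYWLLALFVTMWTDVGLCKKRPKP
MDAQTRRRERRAEKQAQWKAAN
MGLGLHLLVLAAALQGAKKKRKV
MPKKKPTPIQLNP
MVKSKIGSWILVLFVAMWSDVGLCKKRPKP
MVTVLFRRLRIRRACGPPRVRV
NAKTRRHERRRKLAIER
PKKKRKV
PKKKRKVALWKTLLKKVLKA
PMLKE
QLALQLALQALQAALQLA
RGGRLSSYSRRRFSTSTGR
RGGRLSYSRRRFSTSTGR
RGGRLSYSRRRFSTSTGRA
RKKRRQRRR
RKSSKPIMEKRRRAR
RQARRNRRRALWKTLLKKVLKA
RQGAARVTSWLGRQLRIAGKRLEGR
RQGAARVTSWLGRQLRIAGKRLEGRSK
RQIKIWFPNRRMKWKK
RQIKIWFQNMRRKWKK
RQIKIWFQNRRMKWKK
RQIKIWFQNRRMKWKKLRKKKKKH
RQIRIWFQNRRMRWRR
RQPKIWFPNRRMPWKK
RRLSSYSSRRRF
RRMKWKK
RRRRRRRRR
RRWRRWWRRWWRRWRR
RVIRVWFQNKRCKDKK
RVTSWLGRQLRIAGKRLEGRSK
SWLGRQLRIAGKRLEGRSK
TAKTRYKARRAELIAERR
TRQARRNRRRWRERQR
TRRNKRNRIQEQLNRK
TRSSRAGLQFPVGRVHRLLRK
TRSSRAGLQWPVGRVHRLLRKGGC
VPALR
VPMLK
VPTLK
VQAILRRNWNQYKIQ
VRLPPPVRLPPPVRLPPP
WFQNRRMKWKK
YGRKKRRQRRR
YGRKKRRQRRRGTSSSSDELSWIIELLEK
YGRKKRRQRRRSVYDFFVWL
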