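>mu-Sparatoxin-Hp1 category=toxin provenance=printed-mature
ADSGGDAGGDAGADDEGSCKWMFQSCEPPAKCCDGWTCYKGRCNLIL
>mu-Sparatoxin-Hp2 category=toxin provenance=printed-mature
DDDKKECIGHMGWCAWTDGECCEGYRCKLWCRKIIDWL
>SYN-TOX-00 category=toxin provenance=synthetic-exemplar
MKKFFIVIMFLFLIVGTAQQPYQGCIPKCSLTGKCCSRICMSCASCQNKECDTCKFQCVT
F
>SYN-TOX-01 category=toxin provenance=synthetic-exemplar
MQLFFFMVVVIFGSAQQDETQEEARYSNLVICPAPDIRACGRWCCWHDRYDCIWQVCCGI
IRGDCGNHAMLVCTFNVTLPCDRV
>SYN-TOX-02 category=toxin provenance=synthetic-exemplar
MKMLLLVMLFMLMVTSAAGSNQQGADERVLSLWYWNCASMHVCLPEWACCENDTWMGCGR
IPMCITVWSL
>SYN-TOX-03 category=toxin provenance=synthetic-exemplar
MQNIFMIMMFMMISTTTEAGSTNGDEARSFLQLYCGFCTECENYSHIQCNWTDSECRHGS
AAMCVESGPKCMWAWYQIWCVPLNKCMVATTSYCWRVMDN
>SYN-TOX-04 category=toxin provenance=synthetic-exemplar
MQKRMLVMIFFMMVMFTSTSSDSNNADQDSGGNGEEARDQFMKWNECPRWLRNFYCRWVS
AVTMCCHLMWDCQDQPIFYCIAQLDRCQRMLVRNCIMQRM
>SYN-TOX-05 category=toxin provenance=synthetic-exemplar
MRKNVFLIFFFVMVFTATMNMCYFMCEYINPEDFCDRIGDDCNLMSSDSWCQQWCCQAWE
IHELCTYAE
>SYN-TOX-06 category=toxin provenance=synthetic-exemplar
MRNRVMMLIVFVVVLLSSSGGEDAQSANNNQAEERPHVWPWDCRRDCAIPGRQCPKLCLW
CDYQICCQGEWWCSMGIMKY
>SYN-TOX-07 category=toxin provenance=synthetic-exemplar
MRVVLVLFLFIVSSGQSTGAAQQQSEDARHDYTPEPCFYWIMDKCHLQLCIHCHDYQDF
>SYN-TOX-08 category=toxin provenance=synthetic-exemplar
MQIIVVIVMFMFIMGGGEHILMCQFHAHYCKNIAWDE
>SYN-TOX-09 category=toxin provenance=synthetic-exemplar
MQVVIMFLLIVFTGAEENNADAEARWDIQSIIVCENQYMCQEVSWWCCTMCGDWDHWLCV
LFGSSEQCNEFTFQCHHLSI
>SYN-TOX-10 category=toxin provenance=synthetic-exemplar
MKIIMLIIMVIIVTTGANQSESEDDRHNQAALICPAAFIIACYTRPCCPMKGARLACPPL
QYCFINY
>SYN-TOX-11 category=toxin provenance=synthetic-exemplar
MNNRLVFIFMIIMVSTGTQTQASQDDEEDRMGWCNQRCTIAKQGTRCCRLDCYGHKMECD
SDMW
>SYN-TOX-12 category=toxin provenance=synthetic-exemplar
MQRILLIVVLMMMLFATGHHYMCETMCVEQVYCCGTRTKQYKCWYDDCFPQ
>SYN-CELL-00 category=cellular provenance=synthetic-exemplar
MLVDLHVCAKFQRSIQCDSWFVAKSDQMVQCLVKYIPSRIWQYYDFVTWADPDMAMMHPV
KLIGDLPNMPPNFDMTRIKHKIVKFLRRHKPYHWAACPDPHFMIEKRVNDNPRLWSFDRF
WVDCTNISKVKFGNTRQWTDDWMVCLTPEVPKTALRPMCFKKTGYMGMPHKFDDPMVMVH
GNPSFPIRLQPAAQERIWFE
>SYN-CELL-01 category=cellular provenance=synthetic-exemplar
MKFCTQFNRLVINTDVQVFFVGGWFEDYLCFMPVKTWAKDEIQGMSNWGCPSIYMPQQNH
TLWRYPFYYQHTDIDIHRDWSTPIRIGMSMTPEWVCWTDVSNWTETCWPPWYQRRSPPLA
YGNIWTRQYDMGGMWWKSRCRLFTPFNPD
>SYN-CELL-02 category=cellular provenance=synthetic-exemplar
MYDSWHEPHIQTSKIDLHDRRNFKFWKAHLIYWSRNCNRCEFKEFPTQSDSNRCMHRGYK
IAMSEAAKAMDHLQHMCYGFPSQHHCGCRHFKHLDFTVACVGREFCKEKNMCVFWGGCFR
HCTKLYAPILRYYINFFRVHNVVGDSSKNKYLIWVPFDYEHLIQNYMLAMQYLKRKV
>SYN-CELL-03 category=cellular provenance=synthetic-exemplar
MRRHVYVFIQCPTNQQDEYFKTKKVIDDPCTFPFNHNDYQFFCFIYTNRKMSEPCKTTYS
FVGCHWTRMKDDQVRNVIYCKDPYLLMRTPGGQICCIGALHNHWQCYEWQSTELFGDHEE
CGIEDKIECSHRGVRQCLVRIASPLIHAPPYDWCCYRAQAWYYHASP
>SYN-CELL-04 category=cellular provenance=synthetic-exemplar
MRMAYHVICTNHWSLMRREKKTFMSSSHPGPRACCPHANCQMSSGNKPNACEAIVENTVV
EGECPYYCMAAIQRWAYVQRSHYQTQVSWRVWKNLWPIWRQNFRLLQTPKTLGPRVGYKN
FLPGYSNALMWPHRRTEYMNSCFVAKDTTKNAAPRSYYVAHMSHGRPCVDHKGFQSRHVR
EQKNMQGPTKMQCCHYETKCEFAFYDRMSGPEYQN
>SYN-CELL-05 category=cellular provenance=synthetic-exemplar
MDPVAPRDIAFSAYIHGLYMSGSRNTMVRMQCDENMDFAYIKIHGLVVWRYKKRKQDTCE
DYFDLLHGDWSDDPVINMHGMVWFQVKCVNFIVFNFKKDGKKCALQTPLDYFYERWVVSG
NQWSEKGGPVMIDEVYLFSRGGGYTITCNDPTSMVYMKTRQYVYWRCHQSERMCVVMLTH
KLTFCMRETPNPDSNAPDPEKQNVVCYDNALELLNNY
>SYN-CELL-06 category=cellular provenance=synthetic-exemplar
MACDCIDFNYHVEIIHHMWDHLNPANLLPCSKEINLQWHLQFTHGNGSFDAILGMHSNHL
ENWSLSTTANMVKDMQWDYAWVHCERVFCQRDAVSNGMIAQCAICTKDCWPDYFNLMRKE
KQFEIRHEMQGKCPFTCPYKELGQPVKEWHEVIMWHTNGGQNALRFTRINAYIEMVIWSL
KGDTQDSERGCVCVPLNAEQQGRLNQEYGYCHQ
>SYN-CELL-07 category=cellular provenance=synthetic-exemplar
MAIGRNYPITVWFEYTSEYSCWGQNRMKYRNVMCMNFHHTEPWAFIYTHTWFRHVKLQVC
LSEPYSPFWMTCFQNWLMKPIWLPFHYQSQIHTIWMFAWYSACFTGNHRAYHHYQKIGVH
DTCSNAAACRKRFFENHLGEWWTGSFPWSVSAHNLQFFGTDDKWEKVEPYWFDGHCCGMQ
PIDTWSNWNVRKMIPDSGGLRGFIQFLSPFVEKFA
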