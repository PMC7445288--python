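peptide	allele	ic50
SQKKVCQF	HLA-A*03:01	6488.669879
YRSRSMDTLM	HLA-A*11:01	6757.974097
WSPKTMKL	HLA-A*07:01	50000
NVCVTGPE	HLA-A*22:01	50000
ICYKVQSSEI	HLA-A*14:01	22462.02543
AMERQWRIY	HLA-A*12:01	21059.21106
WICLSELDQ	HLA-A*14:01	1344.745789
FNQWKETPR	HLA-A*03:01	19887.38471
STKTTIVGF	HLA-A*20:01	19180.05811
DTETASSSQL	HLA-A*21:01	50000
SNLMNADFD	HLA-A*13:01	50000
QLVNCSNPNN	HLA-A*03:01	50000
SHPAHKYFGK	HLA-A*29:01	50000
AFTCVGWGKQD	HLA-A*17:01	50000
SYQKKKTHEH	HLA-A*01:01	50000
CSRQLREW	HLA-A*15:01	3125.724461
ELQLKEIFHQP	HLA-A*18:01	50000
YCHDHYIWL	HLA-A*21:01	34884.50616
GSYGSGRSK	HLA-A*22:01	5348.257176
CCKWDLRFR	HLA-A*09:01	50000
NMELVASLRQK	HLA-A*09:01	23905.21595
DNCPPCSKSA	HLA-A*06:01	50000
EHQDQDENS	HLA-A*05:01	50000
WYNKHPNGA	HLA-A*05:01	40113.58533
KLLSCCGLQLK	HLA-A*28:01	19941.08246
NMLTGYHM	HLA-A*16:01	40645.33322
KGAITAVMDHN	HLA-A*10:01	50000
QQDGFQRR	HLA-A*28:01	758.8614251
HDPWYFFADNM	HLA-A*11:01	50000
TLTYHFYPG	HLA-A*19:01	50000
WGYWEEMAGK	HLA-A*29:01	50000
EVCRTVFVDML	HLA-A*10:01	5175.39538
SHQKIVCR	HLA-A*22:01	26801.19431
GAWWFADCT	HLA-A*26:01	8830.547397
REINRVAE	HLA-A*09:01	28576.42228
YSHYLMKDW	HLA-A*01:01	14659.75702
FGDAQYDG	HLA-A*15:01	2042.695651
QSNKEVTARCR	HLA-A*24:01	50000
KDNWCIYH	HLA-A*04:01	838.9763027
MQHYMGYWL	HLA-A*01:01	50000
NDPTDRDRKA	HLA-A*29:01	50000
NEWRTKLP	HLA-A*23:01	50000
AQDGTGSLFHM	HLA-A*23:01	13513.22122
WVSPGKDIWK	HLA-A*04:01	10638.51833
YVGLMFGFYR	HLA-A*25:01	50000
YDVCLNIDETH	HLA-A*09:01	50000
DWWNEEGNELD	HLA-A*16:01	50000
RCEETCKN	HLA-A*15:01	50000
TITHYMRVSV	HLA-A*16:01	50000
LEVFFFPN	HLA-A*28:01	50000
GAAIWMVDC	HLA-A*25:01	50000
CKWQCTTT	HLA-A*27:01	50000
YHTNSPPP	HLA-A*23:01	4655.259337
DTMHMYVTLS	HLA-A*12:01	12678.38795
PFGCDKLEKP	HLA-A*07:01	50000
IMIRHKIEQ	HLA-A*07:01	50000
SWQWVLSHL	HLA-A*16:01	50000
TLQFTNMSPCG	HLA-A*06:01	50000
AFNQMVWDYP	HLA-A*19:01	22179.77126
PRNCMWRD	HLA-A*28:01	44758.01601
ETKNKSYSWWC	HLA-A*08:01	10082.48414
NCCMPEEDNA	HLA-A*17:01	50000
LQMRSWSML	HLA-A*07:01	30803.99656
DWTDSDRCLQ	HLA-A*22:01	28800.73583
WSFQRHRVT	HLA-A*23:01	3351.603967
GSIMHHEYDC	HLA-A*28:01	21723.83829
KRIDRENWWI	HLA-A*23:01	50000
LDIQYARTYK	HLA-A*04:01	50000
VVPDDLNAQ	HLA-A*16:01	7602.464177
CLRTKGYL	HLA-A*10:01	50000
AHMWRSMDI	HLA-A*29:01	1939.589775
VQGSTADQ	HLA-A*29:01	50000
QDQPCQVV	HLA-A*01:01	23304.98266
FLDVSTEA	HLA-A*27:01	8005.318307
QWAAAECTP	HLA-A*29:01	50000
YFGTFCQTYWD	HLA-A*23:01	50000
QTTKALFDDQM	HLA-A*16:01	338.5985426
MPCVKETRCE	HLA-A*01:01	50000
CRMYRPMCC	HLA-A*18:01	50000
AFVLRKEI	HLA-A*03:01	50000
EIYNLMSGPVN	HLA-A*13:01	13135.82542
FWMHKNMQ	HLA-A*08:01	9324.989948
KWEDLMQKWL	HLA-A*04:01	523.1638995
YDWGCHPK	HLA-A*23:01	35438.58974
KPYKEKTFWN	HLA-A*18:01	2411.501528
WAGKLLDFC	HLA-A*17:01	50000
NNRMPNQPH	HLA-A*08:01	1492.637341
HMEKMPMIYMT	HLA-A*22:01	50000
VDWVMRMGSF	HLA-A*10:01	50000
TILADCCVTT	HLA-A*02:01	50000
GNHLERHC	HLA-A*22:01	50000
AKTRVKIREFP	HLA-A*20:01	50000
MIMYCYKS	HLA-A*13:01	50000
SQDRSIWPH	HLA-A*01:01	5179.278419
FSMLEREKTW	HLA-A*29:01	11597.63698
NFTTYQDMKTI	HLA-A*10:01	21260.15949
TSAKLLWE	HLA-A*09:01	50000
FWWAPFEG	HLA-A*06:01	50000
YNRLACGFT	HLA-A*25:01	1376.39521
PNPKQSSPCRI	HLA-A*22:01	50000
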