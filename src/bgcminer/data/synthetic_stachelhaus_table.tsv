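code10	code34	substrate	source_id
CTDMHMYNCA	RNVYYMYLGMNQCLATAVDSCPEPQINYWRALWK	Ala	SYNREF_0001
HTDMHMYNCA	RNVYYKYLGMNQCLATRVQSCPEPQINYCMALVK	Arg	SYNREF_0002
CHHWHMENVA	CNVYYKYLCMNQCLALAVDSCPTPQISYWMILWK	Asn	SYNREF_0003
CTDMHMYNCA	LNVYYKYRGMCQFLATAVDSCPYPTGNYNMALWK	Asp	SYNREF_0004
PTDMHSHNLA	RNVYLKYLFMNQCLATASHSCPEYQINPWMALNK	Cys	SYNREF_0005
CTDMHMYRGA	RNVLYKYLGHVQLLNTAVDMCPEPQMNYWMILWK	Gln	SYNREF_0006
CTDMHMYNIA	RNWYADYLGMNCCLYTAVDSCPVPQIWAWMALWK	Glu	SYNREF_0007
CTPMHMYNCA	RNVYYQYLGMNVCLATAIDSPPEPQINYWNALPM	Gly	SYNREF_0008
CTDMHMYNCA	RVVYLKMPRMHQCLAQAVDSCPSPQINYWMALWK	His	SYNREF_0009
CTDNHMYNFA	RNVYSKYFHMNQCPAHAVDSCPEPQINYWMATWK	Ile	SYNREF_0010
CTYMHCYNCA	RNFYYKYTGMNVCLANAVDSCPWPEWNYWMALWH	Leu	SYNREF_0011
CTDMHMYNCA	RNVYYKYLCMMQTLATGVDCCEEPQINYWMALWK	Lys	SYNREF_0012
CRDVHMYNCW	RNVPAHYLGMNQCLATAVDMIPVPQGNYWMVLWK	Met	SYNREF_0013
CTCMHMYNCE	RNVYYKYLGMNQCLACAVDSCPEPQINYWMNLWH	Phe	SYNREF_0014
CDDMHMYCCA	RGVHYKYLGMEQSTRQMVDSGPEPQINYHRMLWK	Pro	SYNREF_0015
WTCNAMYNCA	INVYYKYLSMNQCLLTAVDSCPMKQINYWVALNW	Ser	SYNREF_0016
CTDMAMGNCA	TNVYYKPLGMNQCLATACDSCPEPRINYWMALWK	Thr	SYNREF_0017
CTDMHTHNCQ	QNVYYKYLGKNQHNALAHQCCPEPQINYWMAVWK	Trp	SYNREF_0018
CTDMHMYLWL	YNVYYRYLGMNQILATVVSSCPEPQMNYRMALWK	Tyr	SYNREF_0019
WTQTHMYNCA	VKVFYKYLGMNNCIATAVDSCPEPWINNWMACWK	Val	SYNREF_0020
CTIMHMYNCA	RNKYDKYLGCFYCLADACDMMPEPQINYWCALSK	Ala	SYNREF_0021
CHDMHMYGPA	RNKYYKYLGMNQCWATAVDSWFEPIINYQTALWK	Arg	SYNREF_0022
CTVMKMYNCI	RTVYDTYLGMNFDLATAVDSCPEQQYNYWMALRK	Asn	SYNREF_0023
CTDMHGTNCA	VNVYYKYLGMDQCLFTAVDSCWMPQIDYWMALWF	Asp	SYNREF_0024
CTIMKMYNCA	SNVYYKYLGMNQCVATAVDSCPECQISYWMALWK	Cys	SYNREF_0025
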