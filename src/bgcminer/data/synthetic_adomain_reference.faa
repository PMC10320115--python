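>synthetic_adomain_reference synthetic stand-in reference A domain
FPDVFNCPLKSSMVITMCLWIPANREQRPMIQIFCAWMHRNAVFNFVGHCFLPPHYNGED
QSWPPTDLMDQPFRSHDTADNVNGEFALGYYIQYFPWEWRALMMDWRGCMETPIVMEEKG
HWAHAVRELSGILCIGHYLWGVDAAPHQQAHEPQAWLVICHKMTCEKWNNGLTVRCMLWF
VMPRSHVIAQKNGKEMHSENFNNPATNPQVRFHSCMIDECFWTTQKRWYIDLLLKTNHNP
YKTIHIYMFKDCVGFMGITDLVPSRLMPWIVVPENGFYTFWQWWTKKNGSFMAQAHTHWP
KIFVGGVMFHSNGFYCRWKCSGSTQFLSDLDAESYDYVLETTYMGQHITGAETGHDYEIE
IMMNMCCQTQCTGQAGVPFYWWTVAVPCDQVRHCKCSMQAYMHCPGNLTMASGMDKHKQD
HSPHHMVWSCQSCAKKMTNSCISHIDRITIITDTRGRASRTEVNRQVKPGLLNYWPPEND
TENGSRIKNMPLENDCDIWH
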