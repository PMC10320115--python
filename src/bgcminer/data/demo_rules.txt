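# Illustrative detection rules. These mimic the *shape* of curated rules
# (core functions, cutoff and neighbourhood distances in kb) but are not
# the published curated rule set; profile names are generic detector ids.
RULE t1pks CATEGORY PKS CUTOFF 20 NEIGHBOURHOOD 20
CONDITIONS cds(PKS_KS and PKS_AT)
RULE nrps CATEGORY NRPS CUTOFF 20 NEIGHBOURHOOD 20
CONDITIONS cds(AMP-binding and Condensation)
RULE terpene CATEGORY Terpene CUTOFF 20 NEIGHBOURHOOD 10
CONDITIONS Terpene_synth or Lycopene_cycl
RULE lanthipeptide CATEGORY RiPP CUTOFF 20 NEIGHBOURHOOD 10
CONDITIONS LANC_like and DUF4135
RULE cyanobactin CATEGORY RiPP CUTOFF 20 NEIGHBOURHOOD 10
CONDITIONS cyanobactin_synth or cyanobactin_precursor
RULE phosphonate-like CATEGORY Other CUTOFF 20 NEIGHBOURHOOD 20
CONDITIONS PEP_mutase
RULE phosphonate CATEGORY Other CUTOFF 20 NEIGHBOURHOOD 20
CONDITIONS PEP_mutase and minimum(1, [Ppd_decarb, Phosphonate_transfer])
RULE nrp-metallophore CATEGORY NRPS CUTOFF 20 NEIGHBOURHOOD 20
CONDITIONS cds(AMP-binding and Condensation) and minimum(1, [Chelator_mono, Chelator_diox, Salicylate_synth])
RULE betalactone CATEGORY Other CUTOFF 10 NEIGHBOURHOOD 10
CONDITIONS HMG_CoA_synth and Lactonase
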