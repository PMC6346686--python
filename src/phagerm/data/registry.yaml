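# Registry of S. aureus R-M recognition specificities of known sequence,
# with per-clonal-complex system assignments and empirical host-range data
# (productively infected / tested, "I/T"; NT = not tested).
#
# printed_count: the published number of targets of each specificity in the
# phiAGO1.3 genome — shipped as reference input data for the host-range and
# concordance analyses.  The CC93 row's printed counts are partially
# ambiguous in the source table; the values below follow the accompanying
# text (no CC93-3 sites, a single CC93-2 site).
sites:
  - {name: CC1-1,   enzyme: S.SauMW2I,          clonal_complex: CC1,   rm_type: TypeI,  notation: CCAY-5-TTAA, printed_count: 1}
  - {name: CC1-2,   enzyme: S.SauMW2II,         clonal_complex: CC1,   rm_type: TypeI,  notation: CCAY-6-TGT,  printed_count: 0, alias: CC8-2}
  - {name: CC5-2,   enzyme: S.SauN315II,        clonal_complex: CC5,   rm_type: TypeI,  notation: CCAY-6-GTAA, printed_count: 3}
  - {name: CC5-1,   enzyme: S.SauN315I,         clonal_complex: CC5,   rm_type: TypeI,  notation: GG-5-GAT,    printed_count: 0, alias: CC8-1}
  - {name: CC15-1,  enzyme: S.SauLT3150RFAP,    clonal_complex: CC15,  rm_type: TypeI,  notation: CAAC-5-RTGA, printed_count: 0}
  - {name: CC22-1,  enzyme: S.Sau5096I,         clonal_complex: CC22,  rm_type: TypeI,  notation: AGG-6-TGAR,  printed_count: 5}
  - {name: CC30-1,  enzyme: S.SauMRSII,         clonal_complex: CC30,  rm_type: TypeI,  notation: GWAG-5-GATG, printed_count: 0}
  - {name: CC30-2,  enzyme: S.SauMRSI,          clonal_complex: CC30,  rm_type: TypeI,  notation: GA-7-TCG,    printed_count: 0}
  - {name: CC45-1,  enzyme: S.Sau347I,          clonal_complex: CC45,  rm_type: TypeI,  notation: GWAG-6-TAAA, printed_count: 0}
  - {name: CC51-1,  enzyme: S.SauL30RFAP,       clonal_complex: CC51,  rm_type: TypeI,  notation: GGA-6-CCT,   printed_count: 0}
  - {name: CC59-1,  enzyme: S.SauSA40ORF370P,   clonal_complex: CC59,  rm_type: TypeI,  notation: GGA-6-RTGT,  printed_count: 1}
  - {name: CC72-1,  enzyme: S.SauCN10RF415P,    clonal_complex: CC72,  rm_type: TypeI,  notation: GARA-6-RTGT, printed_count: 1}
  - {name: CC72-2,  enzyme: S.SauCN10RF1757P,   clonal_complex: CC72,  rm_type: TypeI,  notation: GGA-7-TGC,   printed_count: 0}
  - {name: CC75-1,  enzyme: S.SauLL32ORF3780P,  clonal_complex: CC75,  rm_type: TypeI,  notation: CAAG-5-RTC,  printed_count: 2}
  - {name: CC75-2,  enzyme: S.SauLL32ORF16570P, clonal_complex: CC75,  rm_type: TypeI,  notation: CNGA-7-TTYG, printed_count: 0}
  - {name: CC93-3,  enzyme: S.SauJKDIII,        clonal_complex: CC93,  rm_type: TypeI,  notation: GAAG-5-TAC,  printed_count: 0}
  - {name: CC93-2,  enzyme: S.SauJKDII,         clonal_complex: CC93,  rm_type: TypeI,  notation: GGHA-7-TCG,  printed_count: 1}
  - {name: CC93-1,  enzyme: S.SauJKDI,          clonal_complex: CC93,  rm_type: TypeI,  notation: CAG-6-TTC,   printed_count: 3}
  - {name: CC97-1,  enzyme: S.SauC01791ORFAP,   clonal_complex: CC97,  rm_type: TypeI,  notation: CCAY-6-RTC,  printed_count: 0}
  - {name: CC133-1, enzyme: S.SauL330RF451P,    clonal_complex: CC133, rm_type: TypeI,  notation: CAG-5-RTGA,  printed_count: 1}
  - {name: CC133-2, enzyme: S.SauL330RF1794P,   clonal_complex: CC133, rm_type: TypeI,  notation: GGA-7-TTRG,  printed_count: 0}
  - {name: CC398-1, enzyme: S.SauSTORF499P,     clonal_complex: CC398, rm_type: TypeI,  notation: ACC-5-RTGA,  printed_count: 5}
  - {name: CC873-1, enzyme: S.Sau323260RFAP,    clonal_complex: CC873, rm_type: TypeI,  notation: GAG-6-GAT,   printed_count: 5}
  - {name: Sau3A,   enzyme: Sau3A,              clonal_complex: null,  rm_type: TypeII, notation: GATC,        printed_count: 2}
  - {name: Sau96I,  enzyme: Sau96I,             clonal_complex: null,  rm_type: TypeII, notation: GGNCC,       printed_count: 0}

# CC8 carries the systems shared with CC1/CC5 (the "(CC8-1)/(CC8-2)"
# aliases above); it therefore references those sites rather than owning
# its own rows.
profiles:
  - {clonal_complex: CC1,   systems: [CC1-1, CC1-2],          i_t: 4/5}
  - {clonal_complex: CC5,   systems: [CC5-2, CC5-1],          i_t: 10/10}
  - {clonal_complex: CC8,   systems: [CC1-2, CC5-1],          i_t: 7/8}
  - {clonal_complex: CC15,  systems: [CC15-1],                i_t: 4/5}
  - {clonal_complex: CC22,  systems: [CC22-1],                i_t: 4/4}
  - {clonal_complex: CC30,  systems: [CC30-1, CC30-2],        i_t: 8/8}
  - {clonal_complex: CC45,  systems: [CC45-1],                i_t: 9/9}
  - {clonal_complex: CC51,  systems: [CC51-1],                i_t: NT}
  - {clonal_complex: CC59,  systems: [CC59-1],                i_t: 1/4}
  - {clonal_complex: CC72,  systems: [CC72-1, CC72-2],        i_t: NT}
  - {clonal_complex: CC75,  systems: [CC75-1, CC75-2],        i_t: NT}
  - {clonal_complex: CC93,  systems: [CC93-3, CC93-2, CC93-1], i_t: NT}
  - {clonal_complex: CC97,  systems: [CC97-1],                i_t: 0/1}
  - {clonal_complex: CC133, systems: [CC133-1, CC133-2],      i_t: NT}
  - {clonal_complex: CC398, systems: [CC398-1],               i_t: 3/4}
  - {clonal_complex: CC873, systems: [CC873-1],               i_t: NT}
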