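# Instrument catalog, version 1.
#
# Item-to-subscale assignment and reversed-item sets are a catalog convention
# (block layout); cut-offs are the published clinical values. ASQ subscale
# cut-offs are mean - 1 SD of an archival outpatient sample; they can be
# recomputed from new archival data with instruments.compute_asq_cutoffs.
version: 1

instruments:
  HSCL11: {n_items: 11, min: 0, max: 3}
  ASC:    {n_items: 40, min: 1, max: 5}
  ASQ:    {n_items: 20, min: 1, max: 5}
  OQ30:   {n_items: 30, min: 1, max: 5}

# Items feeding the risk/suicidality domain. The HSCL-11 suicidal-ideation
# item is answered every session; the OQ-30 items only at battery sessions
# and are carried forward in between. Direction is at-or-above.
risk_items:
  - {instrument: HSCL11, item: 11, cutoff: 2, immediate: true}
  - {instrument: OQ30,   item: 5,  cutoff: 3, immediate: false}
  - {instrument: OQ30,   item: 18, cutoff: 3, immediate: false}

scales:
  HSCL_total:
    instrument: HSCL11
    items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11]
    reversed: []
    aggregation: mean
    domain_cutoff: null
    cutoff_direction: at_or_above   # impairment scale: higher = worse
    item_cutoff: null
  ASC_TA:
    instrument: ASC
    items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11]
    reversed: [4, 8]
    aggregation: sum
    domain_cutoff: 39
    cutoff_direction: at_or_below
    item_cutoff: 2
  ASC_SS:
    instrument: ASC
    items: [12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22]
    reversed: [18, 22]
    aggregation: sum
    domain_cutoff: 23
    cutoff_direction: at_or_below
    item_cutoff: 2
  ASC_MO:
    instrument: ASC
    items: [23, 24, 25, 26, 27, 28, 29, 30, 31]
    reversed: [25, 27]
    aggregation: sum
    domain_cutoff: 32
    cutoff_direction: at_or_below
    item_cutoff: 2
  ASC_LE:
    instrument: ASC
    items: [32, 33, 34, 35, 36, 37, 38, 39, 40]
    reversed: [32, 33, 34, 35, 36, 37, 38, 39, 40]
    aggregation: sum
    domain_cutoff: 23
    cutoff_direction: at_or_below
    item_cutoff: 2
  ASQ_concealing:
    instrument: ASQ
    items: [1, 2, 3, 4, 5, 6, 7, 8]
    reversed: [1, 2, 3, 4, 5, 6, 7, 8]
    aggregation: mean
    domain_cutoff: 2.27
    cutoff_direction: at_or_below
    item_cutoff: 2
  ASQ_tolerating:
    instrument: ASQ
    items: [9, 10, 11, 12, 13]
    reversed: []
    aggregation: mean
    domain_cutoff: 2.29
    cutoff_direction: at_or_below
    item_cutoff: 2
  ASQ_adjusting:
    instrument: ASQ
    items: [14, 15, 16, 17, 18, 19, 20]
    reversed: []
    aggregation: mean
    domain_cutoff: 1.70
    cutoff_direction: at_or_below
    item_cutoff: 2
  OQ_total:
    instrument: OQ30
    items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15,
            16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30]
    reversed: []
    aggregation: sum
    domain_cutoff: null
    cutoff_direction: at_or_above
    item_cutoff: null
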