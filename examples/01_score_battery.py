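"""Score one patient's battery and evaluate the clinical cut-offs.

Builds a single assessment (ASC, ASQ and the three risk items), scores the
scales with reversal and mean-imputation rules, and prints which domains
cross their warning cut-offs.
"""

from otrack.instruments import (ItemResponse, default_catalog, domain_flag,
                                item_flags, recode_reversed, risk_assessment,
                                score_scale)

catalog = default_catalog()

# Raw Likert responses (1-5) keyed by ASC/ASQ item id.  This patient reports
# many distressing life events (high raw values on the reversed LE items ->
# low functioning after recoding) and a thin support network.
raw = {"ASC": {}, "ASQ": {}}
for item in catalog["ASC_TA"].item_ids:
    raw["ASC"][item] = 5 if item not in (4, 8) else 1   # good alliance
for item in catalog["ASC_SS"].item_ids:
    raw["ASC"][item] = 2 if item not in (18, 22) else 4  # weak support
for item in catalog["ASC_MO"].item_ids:
    raw["ASC"][item] = 4 if item not in (25, 27) else 2
for item in catalog["ASC_LE"].item_ids:
    raw["ASC"][item] = 4                                 # reversed: many events
for item in catalog["ASQ_concealing"].item_ids:
    raw["ASQ"][item] = 2                                 # reversed
for item in catalog["ASQ_tolerating"].item_ids:
    raw["ASQ"][item] = 3
for item in catalog["ASQ_adjusting"].item_ids:
    raw["ASQ"][item] = 2

print(f"{'scale':<16}{'score':>8}{'cutoff':>8}  crossed  critical items")
for name in (*catalog.asc_scales, *catalog.asq_scales):
    scale = catalog[name]
    resp = [ItemResponse(scale.instrument, i, raw[scale.instrument.value][i])
            for i in scale.item_ids]
    recoded = recode_reversed(resp, scale)
    score = score_scale(recoded, scale)
    crossed = domain_flag(score, scale)
    critical = sorted(item_flags(recoded, scale))
    print(f"{name:<16}{score.value:>8.2f}{scale.domain_cutoff:>8.2f}"
          f"  {str(crossed):<7}  {critical}")

risk = risk_assessment(
    ItemResponse("HSCL11", 11, 2),   # suicidal ideation 'quite a lot'
    ItemResponse("OQ30", 5, 1),
    ItemResponse("OQ30", 18, 1),
)
print(f"\nrisk/suicidality: severity {risk.severity}/3, flag={risk.flag}, "
      f"immediate alert={risk.immediate}")
print("\nA crossed scale means the domain would flag orange for a patient "
      "who is off track;\nthe immediate alert fires regardless of track "
      "status.")
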