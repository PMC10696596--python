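"""The post-search filter cascade with neutral-loss reconciliation.

Builds a small PSM table (with a duplicate scan, a non-consensus site and
a sulfopeptide mis-annotated as phospho), links it to simulated survey
scans, and runs the cascade.
"""

from sulfoscan import PSMRecord, SimParams, classify, neutral_loss_report, parse_peptide
from sulfoscan.psm import cascade, sites_to_frame
from sulfoscan.simulate import simulate_low_nce_scan

params = SimParams(seed=5)
survey = simulate_low_nce_scan(parse_peptide("EDFED[sY]EFDGK"), 2, params, params.rng(), scan_id=1)
nl = {1: classify(neutral_loss_report(survey))}

psms = [
    # the search engine cannot distinguish the isobaric pair: annotated pY
    PSMRecord(2, parse_peptide("EDFED[pY]EFDGK"), "STC2", score=48.0, ppm_error=0.4),
    PSMRecord(2, parse_peptide("EDFED[pY]EFDGK"), "STC2", score=31.0, ppm_error=1.0),
    PSMRecord(3, parse_peptide("AAAA[sY]AAAA"), "X1", score=25.0),   # no consensus
    PSMRecord(4, parse_peptide("AGLK"), "X2", score=12.0),           # unmodified
]
sites, funnel = cascade(psms, classifications=nl, links={2: 1})

print(funnel.to_string(index=False))
print()
print(sites_to_frame(sites).to_string(index=False))
print("\n-> the duplicate scan collapses, the non-consensus site is dropped,")
print("   and the surviving site is re-called sulfo from its -80 evidence.")
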