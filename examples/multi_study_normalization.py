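"""Percent-of-control pooling of a target gene across heterogeneous studies.

Simulates six studies whose linear-scale intensities differ by up to 20x and
which share a 0.7-fold down-regulation of TSC1/TSC2 in cases, then expresses
every sample as a percentage of its own study's control mean so the studies
pool onto one scale.
"""

from sigscore import MultiStudyConfig, cross_study_percent, generate_multi_study

studies = generate_multi_study(MultiStudyConfig(seed=4))

for gene in ("TSC1", "TSC2"):
    table = cross_study_percent(studies, gene)
    by_group = table.groupby("group")["percent_of_control"].mean().round(1)
    print(f"{gene}: pooled mean % of control  {by_group.to_dict()}  "
          f"({table['study_id'].nunique()} studies, {len(table)} samples)")
print(
    "\nControls average exactly 100 within every study; the case mean "
    "recovers the planted 0.7 fold (~70%) despite the study scale differences."
)
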