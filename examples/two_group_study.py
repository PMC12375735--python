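"""A simulated knockout-vs-control vascular study, end to end.

Generates a two-group study in which the "KO" group has fewer short
branches and fewer large-radius vessels, renders every sample, runs the
measurement pipeline, and prints the group statistics: per-metric Student
t-tests and the repeated-measures group x length-bin interaction.
"""

import tempfile
from pathlib import Path

from vesselmorph import PipelineConfig, run_study
from vesselmorph.synthetic import StudyDesign, generate_study, write_study

design = StudyDesign(seed=0)  # n = 5 per group, KO multipliers 0.3
workdir = Path(tempfile.mkdtemp(prefix="vesselmorph_study_"))
write_study(generate_study(design), workdir)

config = PipelineConfig(
    pixel_size_override=1.0,
    min_object_px=30,       # drop sub-vessel noise specks
    prune_spurs_um=12.0,    # remove skeleton twigs below the shortest branch
    junction_merge_um=12.0, # merge split junction blobs of wide vessels
)
study = run_study(workdir / "manifest.csv", config)

print(study.summary[study.summary["metric"].isin(
    ["branch_density", "large_radius_total_um"])].to_string(index=False))
print()
print(study.t_tests[["metric", "t", "p", "significant"]].to_string(index=False))
it = study.interaction
print(
    f"\nbranch-length distribution: interaction "
    f"F({int(it.df[0])},{int(it.df[1])}) = {it.statistic:.2f}, p = {it.p_value:.2e}"
)
print(study.posthoc[["bin", "p", "p_bonferroni"]].to_string(index=False))
# Branch density and large-radius total length drop significantly in KO,
# and the interaction says the group difference is concentrated in specific
# length bins (the short-branch bins, by design).
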