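"""End-to-end study run from a manifest.

Simulates a tiny two-genotype study to disk (twitch/tetanus pairs plus one
ECD protocol per subject), builds the manifest CSV, runs the orchestrated
pipeline and prints the group summary table — the same path as the
``musclephys run`` CLI command.
"""

import tempfile
from pathlib import Path

import pandas as pd

from musclephys import (CohortSpec, RunConfig, StudyManifest, TetanusParams,
                        TwitchParams, run_study, simulate_cohort,
                        simulate_tetanus, simulate_twitch)
from musclephys.io_core import write_trace

root = Path(tempfile.mkdtemp(prefix="musclephys_study_"))
rows = []
for genotype, dec_mean, dec_sd, plateau, seed in (
        ("WT", 17.0, 11.0, 8.0, 31), ("DE50-MD", 76.0, 14.0, 4.0, 32)):
    protocols, truth = simulate_cohort(CohortSpec(
        genotype=genotype, decrement_mean_pct=dec_mean, decrement_sd_pct=dec_sd,
        n_subjects=3, plateau_Nm=plateau, noise_sd_Nm=0.01, seed=seed))
    for i, ((traces, _), meta) in enumerate(zip(protocols, truth.itertuples())):
        sid = meta.subject_id
        subject = dict(subject_id=sid, genotype=genotype, age_months=12.0)
        common = dict(subject_id=sid, genotype=genotype, age_months=12.0,
                      bodyweight_kg=12.0, lever_arm_m=0.11)
        tw = simulate_twitch(TwitchParams(
            amplitude_Nm=plateau / 4, noise_sd_Nm=0.005, seed=seed * 100 + i,
            subject=subject))
        te = simulate_tetanus(TetanusParams(
            plateau_Nm=plateau, noise_sd_Nm=0.005, seed=seed * 200 + i,
            subject=subject))
        for kind, tr in (("twitch", tw), ("tetanus", te)):
            p = write_trace(tr, root / sid / f"{kind}.csv")
            rows.append({**common, "protocol": kind, "path": str(p)})
        for tr in traces:
            p = write_trace(tr, root / sid /
                            f"ecc_{int(tr.extra['protocol_index']):02d}.csv")
            rows.append({**common, "protocol": "eccentric", "path": str(p)})

manifest_path = root / "manifest.csv"
pd.DataFrame(rows).to_csv(manifest_path, index=False)
print(f"study written to {root} ({len(rows)} files)")

bundle = run_study(StudyManifest.from_csv(manifest_path), RunConfig(),
                   out_dir=root / "results")
print(f"per-subject errors: {bundle['errors'] or 'none'}")
print("\nECD results per subject:")
print(bundle["ecd"][["subject_id", "genotype", "max_abs_force_N",
                     "final_decrement_pct"]].round(2).to_string(index=False))
print("\ngroup summary (mean / sd / n per genotype):")
summary = bundle["summary"]
print(summary[summary["metric"].isin(
    ["final_decrement_pct", "relative_force_N_per_kg"])]
    .round(2).to_string(index=False))
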