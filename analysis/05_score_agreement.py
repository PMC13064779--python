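"""Agreement between checklist-derived and severity-derived person scores.

Loads the testlet propensity scores (03) and the GRM severity scores (04),
computes Spearman rank correlations (scores vs raw symptom counts, and
between the two scoring routes), runs the Bland-Altman agreement procedure
with joint posterior SEs at z = 1.96, and writes the per-person records and
plot coordinates under results/.
"""

import json
from pathlib import Path

from ocdim.agreement import bland_altman, score_vs_raw_rank_check, write_plot_coords
from ocdim.datasets import read_responses
from ocdim.tables import FLOAT_FMT, PersonScoreTable

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    resp = read_responses(ROOT / "data" / "responses.csv")
    checklist = PersonScoreTable.read(ROOT / "checklist_scores.csv")
    severity = PersonScoreTable.read(ROOT / "severity_scores.csv")

    rho_raw = score_vs_raw_rank_check(checklist, resp)
    print(f"Spearman(model score, raw symptom count) = {rho_raw:.3f}")

    records, summary = bland_altman(checklist, severity, z=1.96)
    records.to_csv(ROOT / "agreement_records.csv", index=False, float_format=FLOAT_FMT)
    write_plot_coords(records, ROOT / "bland_altman_coords.csv")
    with open(ROOT / "agreement_summary.json", "w") as fh:
        json.dump({k: v for k, v in summary.items() if k != "disagreements"}, fh, indent=1)

    print(f"Spearman(checklist score, severity score) = {summary['spearman']:.3f}")
    print(
        f"Bland-Altman agreement at z=1.96: {summary['percent_agree']:.1f}% "
        f"of {summary['n_compared']} persons "
        f"({summary['n_excluded']} excluded for missing scores)"
    )
    print(f"largest disagreements: {summary['disagreements'][:5]}")


if __name__ == "__main__":
    main()
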