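#!/usr/bin/env python
"""Score the AUT tables: fluency, flexibility, frequency-based and
rater-based originality per participant, plus inter-rater reliability.

Writes results/participant_scores.csv.
"""

from pathlib import Path

import pandas as pd

from ebrdt import compute_icc, score_participants

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    responses = pd.read_csv(OUT / "aut_responses.csv")
    sebr = (pd.read_csv(OUT / "sebr_measured.csv")
            .set_index("participant_id")["sebr_measured"])
    scores = score_participants(responses, sebr=sebr)
    scores.to_csv(OUT / "participant_scores.csv")
    icc = compute_icc(responses[["rater1_score", "rater2_score"]].to_numpy())
    print(f"scored {len(scores)} participants over "
          f"{responses['object_id'].nunique()} objects")
    print(scores.describe().loc[["mean", "std"]].round(3).to_string())
    print(f"inter-rater reliability on {icc.n_items} ideas: "
          f"ICC = {icc.icc:.3f}  [{icc.variant}]")


if __name__ == "__main__":
    main()
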