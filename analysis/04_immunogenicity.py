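"""Class I pMHC immunogenicity scores per productive CDR3 peptide, the
per-sample percent-positive summary, and an F-test comparing score
variances between the two clinical groups.

Writes results/immunogenicity.tsv and results/immunogenicity_summary.tsv.
"""

import pandas as pd

from _common import RESULTS, ensure_cohort
from cdr3profile.immunogenicity import (load_default_model, score_peptide,
                                        summarize_immunogenicity,
                                        variance_f_test)
from cdr3profile.translate import productive


def main():
    cohort = ensure_cohort()
    RESULTS.mkdir(exist_ok=True)
    model = load_default_model()

    rows, summaries = [], []
    scores_by_group = {}
    for rep in cohort.repertoires:
        scores = [score_peptide(r.cdr3_aa, model) for r in productive(rep)]
        for s in scores:
            rows.append({"sample_id": rep.sample_id, "cdr3_aa": s.cdr3_aa,
                         "score": s.score, "positive": s.positive})
        summ = summarize_immunogenicity(scores, rep.sample_id)
        summaries.append({"sample_id": summ.sample_id,
                          "group": rep.group.value,
                          "positive_scoring": summ.positive_count,
                          "total_sequences": summ.total_count,
                          "percent_immunogenic": summ.percent_positive})
        scores_by_group.setdefault(rep.group.value, []).extend(
            s.score for s in scores)

    pd.DataFrame(rows).to_csv(RESULTS / "immunogenicity.tsv", sep="\t",
                              index=False)
    summary = pd.DataFrame(summaries)
    summary.to_csv(RESULTS / "immunogenicity_summary.tsv", sep="\t",
                   index=False)
    print("per-sample immunogenicity summary:")
    print(summary.to_string(index=False))

    F, p = variance_f_test(scores_by_group["ARDS"],
                           scores_by_group["non_ARDS"])
    print(f"\nscore-variance F-test ARDS vs non-ARDS: F = {F:.3f}, "
          f"p = {p:.3g} (test choice is method-dependent)")


if __name__ == "__main__":
    main()
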