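"""Theoretical isoelectric points per productive CDR3 peptide and
residue-property composition per sample and per clinical group.

Writes results/isoelectric_points.tsv and results/composition.tsv.
"""

import pandas as pd

from _common import RESULTS, ensure_cohort
from cdr3profile.biochem import isoelectric_point, residue_composition
from cdr3profile.translate import productive


def main():
    cohort = ensure_cohort()
    RESULTS.mkdir(exist_ok=True)

    rows = []
    for rep in cohort.repertoires:
        for r in productive(rep):
            rows.append({"sample_id": rep.sample_id,
                         "group": rep.group.value, "cdr3_aa": r.cdr3_aa,
                         "pI": isoelectric_point(r.cdr3_aa).pI})
    pis = pd.DataFrame(rows)
    pis.to_csv(RESULTS / "isoelectric_points.tsv", sep="\t", index=False)
    by_sample = pis.groupby(["sample_id", "group"])["pI"].agg(
        ["mean", "min", "max", lambda s: 100 * (s < 7).mean()])
    by_sample.columns = ["mean_pI", "min_pI", "max_pI", "pct_below_7"]
    print("isoelectric points of productive CDR3 peptides:")
    print(by_sample.round(2).to_string())

    frames = []
    by_group = {}
    for rep in cohort.repertoires:
        peps = [r.cdr3_aa for r in productive(rep)]
        df = residue_composition(peps).to_frame()
        df.insert(0, "scope", rep.sample_id)
        frames.append(df)
        by_group.setdefault(rep.group.value, []).extend(peps)
    for gname, peps in by_group.items():
        df = residue_composition(peps).to_frame()
        df.insert(0, "scope", f"group:{gname}")
        frames.append(df)
    comp = pd.concat(frames, ignore_index=True)
    comp.to_csv(RESULTS / "composition.tsv", sep="\t", index=False)
    print("\nresidue-property composition, pooled per group (%):")
    pooled = comp[comp.scope.str.startswith("group:")]
    print(pooled.pivot(index="group", columns="scope",
                       values="percentage").round(2).to_string())


if __name__ == "__main__":
    main()
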