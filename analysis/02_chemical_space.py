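#!/usr/bin/env python
"""Profile the chemical space of the generated library: Ro5 descriptor
distributions per modality and a MACCS/Tanimoto UMAP embedding.

Heterobifunctional degraders should sit clearly above the glues and
conventional compounds in molecular weight (and mostly beyond the rule of
five), and should cluster apart in the 2-D embedding.

Writes descriptor and embedding tables to results/run/reports/ plus a
two-panel figure.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from tpd_qspr.assay_data import read_compounds_csv
from tpd_qspr.chemistry import (EmbeddingConfig, descriptor_table,
                                embed_chemical_space, maccs_fingerprint)
from tpd_qspr.pipeline import RunConfig, run_pipeline, stage_seed

CONFIG = Path(__file__).with_name("config.yaml")
PALETTE = {"glue": "tab:blue", "heterobifunctional": "tab:orange", "other": "tab:green"}


def main() -> None:
    cfg = RunConfig.from_yaml(CONFIG)
    run_pipeline(cfg, ["generate"])
    out = Path(cfg.out_dir)
    reports = out / "reports"
    reports.mkdir(parents=True, exist_ok=True)

    molecules = read_compounds_csv(out / "compounds.csv")
    desc = descriptor_table(molecules)
    desc.to_csv(reports / "descriptors.csv", index=False)

    summary = desc.groupby("modality")[
        ["mw", "hba", "hbd", "tpsa", "clogp", "rotatable_bonds"]].median()
    print("median descriptor values per modality:")
    print(summary.round(1).to_string())
    bro5 = desc.groupby("modality")["beyond_ro5"].mean().mul(100)
    print("\npercent beyond rule-of-five (default >1 violation):")
    print(bro5.round(1).to_string())

    fps = [maccs_fingerprint(m) for m in molecules]
    coords = embed_chemical_space(fps, EmbeddingConfig(),
                                  seed=stage_seed(cfg.seed, "generate"))
    emb = pd.DataFrame({"compound_id": desc.compound_id,
                        "modality": desc.modality,
                        "umap_x": coords[:, 0], "umap_y": coords[:, 1]})
    emb.to_csv(reports / "embedding.csv", index=False)

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    data = [desc.loc[desc.modality == m, "mw"] for m in PALETTE]
    axes[0].boxplot(data, tick_labels=list(PALETTE), whis=1.5, showfliers=False)
    axes[0].set_ylabel("molecular weight (Da)")
    axes[0].set_title("MW by modality")
    for m, color in PALETTE.items():
        sub = emb[emb.modality == m]
        axes[1].scatter(sub.umap_x, sub.umap_y, s=4, alpha=0.5, c=color, label=m)
    axes[1].legend(markerscale=3)
    axes[1].set_title("UMAP of MACCS keys (Tanimoto)")
    fig.tight_layout()
    fig.savefig(reports / "chemical_space.png", dpi=150)
    print(f"\nwrote {reports/'descriptors.csv'}, {reports/'embedding.csv'}, "
          f"{reports/'chemical_space.png'}")


if __name__ == "__main__":
    main()
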