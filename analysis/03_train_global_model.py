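#!/usr/bin/env python
"""Train the multi-task GNN on pre-cutoff compounds.

Trains the ensemble on everything registered through the temporal cutoff
(masked loss over the sparse label matrix, scaffold-held-out early
stopping) and saves the checkpoint. Prints the training audit.
"""

import json
from pathlib import Path

from tpd_qspr.model import load_checkpoint
from tpd_qspr.pipeline import RunConfig, run_pipeline

CONFIG = Path(__file__).with_name("config.yaml")


def main() -> None:
    cfg = RunConfig.from_yaml(CONFIG)
    status = run_pipeline(cfg, ["generate", "train"])
    print(f"pipeline: {status}")

    ensemble = load_checkpoint(Path(cfg.out_dir) / "model.npz")
    audit = ensemble.audit
    print(f"\ntrained on {audit['n_train']} compounds "
          f"({audit['n_validation']} scaffold-held-out for early stopping)")
    for member in audit["members"]:
        best = member["best_epoch"]
        print(f"member {member['member']}: best epoch {best}, "
              f"validation masked loss {member['best_val_loss']:.4f} "
              f"({len(member['epochs'])} epochs run)")


if __name__ == "__main__":
    main()
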