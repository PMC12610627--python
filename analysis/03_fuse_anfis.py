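#!/usr/bin/env python
"""Fuse EEG and questionnaire scores with the ANFIS, supervised by behavior.

Trains the 4-rule Takagi-Sugeno model on the full score table, reports
grouped leave-one-participant-out RMSE and R^2, and writes the fused table,
the fitted model and the input-output fusion surface under results/.
"""
import argparse
from pathlib import Path

import pandas as pd

from trustfuse import anfis, io
from trustfuse.pipeline import fuse_scores


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--table", type=Path, default=Path("results/score_table.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--epochs", type=int, default=100)
    ap.add_argument("--lr", type=float, default=0.01)
    args = ap.parse_args()

    table = pd.read_csv(args.table)
    fused, model, info = fuse_scores(table, epochs=args.epochs, lr=args.lr)
    args.out.mkdir(parents=True, exist_ok=True)
    fused.to_csv(args.out / "score_table_fused.csv", index=False)
    io.write_model_json(model, args.out / "anfis_model.json", training_config=info)
    axis, surface = anfis.fusion_surface(model)
    io.write_surface_csv(axis, surface, args.out / "fusion_surface.csv")

    print(f"training RMSE = {info['training_rmse']:.3f} (best epoch {info['best_epoch']})")
    cv = info["loocv"]
    print(f"grouped LOOCV: RMSE = {cv['rmse']:.3f}, R^2 = {cv['r_squared']:.3f} "
          f"over {cv['n_folds']} participant folds")
    print(f"fusion surface ({surface.shape[0]}x{surface.shape[1]}) -> {args.out / 'fusion_surface.csv'}")


if __name__ == "__main__":
    main()
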