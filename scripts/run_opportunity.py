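"""Full Opportunity experiment run (requires the downloaded UCI dataset).

Reads the per-run .dat files, keeps the five upper-body IMUs and the
gesture track (17 gestures + null) at 30 Hz, and runs the baseline plus
the complete 115-setting attention grid with 0.5 LSTM dropout (the
null-dominated stream overfits without it).  Takes hours on a CPU.

Usage:
    python scripts/run_opportunity.py --data-dir /path/to/OpportunityUCIDataset/dataset \
        --out results/opportunity_grid.csv [--epochs 50] [--eval-mode 5fold]
"""

import argparse
import glob
from pathlib import Path

from cbamhar.data import (
    opportunity_class_names,
    read_opportunity,
    split_holdout,
    windows_from_recordings,
)
from cbamhar.experiments import run_grid


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", required=True)
    ap.add_argument("--out", required=True)
    ap.add_argument("--epochs", type=int, default=50)
    ap.add_argument("--eval-mode", choices=["holdout", "5fold"],
                    default="holdout")
    ap.add_argument("--window", type=int, default=30, help="samples at 30 Hz")
    ap.add_argument("--overlap", type=float, default=0.5)
    ap.add_argument("--dropout", type=float, default=0.5)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    paths = sorted(glob.glob(str(Path(args.data_dir) / "**" / "*.dat"),
                             recursive=True))
    recs = read_opportunity(paths)
    ds = windows_from_recordings(recs, args.window, args.overlap,
                                 opportunity_class_names())
    ds = split_holdout(ds, seed=args.seed)
    run_grid(ds, eval_mode=args.eval_mode, seed=args.seed, epochs=args.epochs,
             lstm_dropout=args.dropout, out_csv=args.out)


if __name__ == "__main__":
    main()
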