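"""Generate the four synthetic study designs used by the downstream analyses.

Writes FCS 3.1 files, a metadata sheet, and a latent truth table per design
under scratch/studies/<design>/.  Everything downstream (02-04) reads only
the FCS files and metadata, never the truth table.
"""

import argparse
from pathlib import Path

from mbecflow.simulate import DESIGNS, generate_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=ROOT / "scratch" / "studies")
    args = parser.parse_args()

    for i, design in enumerate(sorted(DESIGNS)):
        out = args.out_dir / design
        metadata = generate_study(design, out, seed=(args.seed + 101 * i) % 2**31)
        n_labeled = (metadata.label == "MBEC").sum()
        print(f"{design:>7}: {len(metadata)} samples ({n_labeled} MBEC-labeled) -> {out}")


if __name__ == "__main__":
    main()
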