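#!/usr/bin/env python
"""Compare a deposited hybrid-structure ensemble against a crystal reference.

Requires locally downloaded coordinate files (none are fetched):

    python scripts/deposited_benchmark.py \
        --ensemble 6f3k.pdb --reference 1y0r.pdb --chain A --out out.json

Reports the per-model and mean backbone (CA) RMSD of the ensemble to the
reference and the ensemble's internal precision, in Å.
"""

import argparse
import json

from emnmr.io import read_backbone_coords
from emnmr.validation import ensemble_precision, ensemble_vs_reference


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--ensemble", required=True,
                    help="multi-MODEL PDB/mmCIF of the computed ensemble")
    ap.add_argument("--reference", required=True,
                    help="reference (crystal) structure PDB/mmCIF")
    ap.add_argument("--chain", default=None,
                    help="chain id to compare (default: all chains)")
    ap.add_argument("--out", default=None, help="write JSON here")
    args = ap.parse_args()

    models = read_backbone_coords(args.ensemble, atom_names=("CA",),
                                  chain=args.chain)
    ref = read_backbone_coords(args.reference, atom_names=("CA",),
                               chain=args.chain)[0]
    result = ensemble_vs_reference(models, ref)
    if len(models) >= 2:
        result["ensemble_precision"] = ensemble_precision(models)
    out = json.dumps(result, indent=1)
    print(out)
    if args.out:
        with open(args.out, "w") as fh:
            fh.write(out + "\n")


if __name__ == "__main__":
    main()
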