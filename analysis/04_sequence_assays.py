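#!/usr/bin/env python
"""The two accessory sequence computations.

(1) In-silico PCR with the diagnostic primer pair OMLO707/OMLO708 on a
synthetic template built to the published product arithmetic (23-nt
primers flanking a 307-nt insert -> 353-bp product), exercising the
degenerate W position of OMLO708.

(2) Codon-level annotation of the resistance-conferring arlS nonsense
mutation on a synthetic 451-codon sensor-kinase CDS: G>T at CDS position
1252, Gly(GGA) codon 418 -> stop (TGA), truncating 34 C-terminal
residues.  Writes results/sequence_assays.json.
"""

import argparse
import json
from pathlib import Path

import phagerm as pm

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=41)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "sequence_assays.json")
    args = parser.parse_args()

    template = pm.make_pcr_template(pm.OMLO707, pm.OMLO708, insert_len=307, seed=args.seed)
    amplicons = pm.find_amplicons(template, pm.OMLO707, pm.OMLO708)

    cds = pm.make_cds_with_codon(451, 418, "GGA", seed=args.seed)
    ann = pm.annotate_cds_substitution(cds, 1252, "T")

    results = {
        "pcr": {
            "primers": {pm.OMLO707.name: pm.OMLO707.sequence,
                        pm.OMLO708.name: pm.OMLO708.sequence},
            "template_length": len(template),
            "products": [
                {"start": a.start, "end": a.end, "length": a.length,
                 "template_orientation": a.template_orientation.value}
                for a in amplicons
            ],
        },
        "variant": {
            "cds_length": len(cds),
            "cds_position": ann.cds_position,
            "codon_index": ann.codon_index,
            "ref_codon": ann.ref_codon,
            "alt_codon": ann.alt_codon,
            "ref_aa": ann.ref_aa,
            "alt_aa": ann.alt_aa,
            "consequence": ann.consequence.value,
            "residues_lost": ann.residues_lost,
        },
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(results, indent=1) + "\n")

    (amp,) = amplicons
    print(f"PCR: {len(amplicons)} product, {amp.length} bp "
          f"(positions {amp.start}-{amp.end} on the template)")
    print(f"variant: {ann.ref_codon}->{ann.alt_codon} at codon {ann.codon_index} "
          f"({ann.consequence.value}); {ann.residues_lost} residues lost")
    print(f"written to {args.out}")


if __name__ == "__main__":
    main()
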