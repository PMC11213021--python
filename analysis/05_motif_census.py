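"""Census of sector-state motifs in the alignment.

The 2-state sector generator is a cartoon of compensatory evolution: each
latent state prefers a particular residue at every sector position, so the
residues at two sector positions should co-occur almost perfectly (like the
proline pair of an active-site loop co-occurring with compensatory residues
elsewhere in the protein).  This driver counts one state's two-position motif
and tabulates its co-occurrence with the same state's residue at a third
sector position, against a non-sector control.

Reads results/data/, writes results/motifs/.
"""

import json
from pathlib import Path

from sectordyn.evaluation import PERMISSIVE
from sectordyn.motifs import (
    PatternSpec,
    cooccurrence,
    count_pattern,
    write_contingency,
)
from sectordyn.msa_io import AMINO_ACIDS, process_msa, read_alignment

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "motifs"
    out.mkdir(parents=True, exist_ok=True)
    aln = read_alignment(ROOT / "data" / "msa.fasta")
    truth = json.loads((ROOT / "data" / "ground_truth.json").read_text())
    proc = process_msa(aln, aln.seq_ids[0], PERMISSIVE)

    sector = truth["sector_positions"]
    profiles = truth["profiles"]  # (n_states, n_sector) residue indices
    state0 = [AMINO_ACIDS[i] for i in profiles[0]]

    motif = PatternSpec.from_triples(
        [(sector[0], {state0[0]}, False), (sector[1], {state0[1]}, False)]
    )
    n_motif = count_pattern(proc, motif)
    print(f"two-position state-0 motif "
          f"({sector[0]}:{state0[0]}, {sector[1]}:{state0[1]}): "
          f"{n_motif} of {proc.alignment.n_sequences} sequences")

    partner = PatternSpec.from_triples([(sector[2], {state0[2]}, False)])
    table = cooccurrence(proc, motif, partner)
    write_contingency(table, out / "cooccurrence_sector.tsv",
                      "motif", "partner")
    print(f"co-occurrence with sector position {sector[2]}:{state0[2]}: "
          f"{table.tolist()} (rows: motif/not, cols: partner/not)")

    # control: same test against a non-sector position, expected independent
    control_pos = next(p for p in range(1, aln.n_columns + 1)
                       if p not in sector)
    control = PatternSpec.from_triples([(control_pos, {state0[2]}, False)])
    table_c = cooccurrence(proc, motif, control)
    write_contingency(table_c, out / "cooccurrence_control.tsv",
                      "motif", "control")
    print(f"control at non-sector position {control_pos}: {table_c.tolist()}")
    print(f"wrote contingency tables under {out}")


if __name__ == "__main__":
    main()
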