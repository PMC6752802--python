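"""Regenerate the bundled synthetic reference data files.

Writes the COIB259 panel, the reference amplicons, and the marker
offsets config under src/fawkit/data/ from the deterministic generator
(fixed seed).  Run from the repository root after changing the
generator; the bundled files are committed so users get a stable panel
without running the generator themselves.
"""

from pathlib import Path

from fawkit.synthdata import make_references

REF_SEED = 20190919  # fixed: the bundled panel must be stable across releases

OUT = Path(__file__).resolve().parents[1] / "src" / "fawkit" / "data"


def main() -> None:
    refs = make_references(REF_SEED)
    OUT.mkdir(parents=True, exist_ok=True)

    with open(OUT / "synthetic_coib259_panel.fasta", "w") as fh:
        for label, seq in refs.panel.entries:
            fh.write(f">{label}\n{seq}\n")

    with open(OUT / "synthetic_reference_amplicons.fasta", "w") as fh:
        for name, seq in (
            ("COIB_CS", refs.coib_amplicon_cs),
            ("COIB_RS", refs.coib_amplicon_rs),
            ("TPI_C", refs.tpi_amplicon_c),
            ("TPI_R", refs.tpi_amplicon_r),
        ):
            fh.write(f">{name}\n{seq}\n")

    offs = refs.offsets
    with open(OUT / "marker_offsets.cfg", "w") as fh:
        fh.write(
            "# marker coordinates as 0-based offsets within the bundled\n"
            "# synthetic amplicons; windows are half-open\n"
            f"coib259_start = {offs.coib259_window[0]}\n"
            f"coib259_end = {offs.coib259_window[1]}\n"
            f"coib296_start = {offs.coib296_window[0]}\n"
            f"coib296_end = {offs.coib296_window[1]}\n"
            f"pos_1164 = {offs.pos_1164}\n"
            f"pos_1287 = {offs.pos_1287}\n"
            f"tpie4i4_start = {offs.tpie4i4_window[0]}\n"
            f"tpie4i4_end = {offs.tpie4i4_window[1]}\n"
            f"pos_tpi183 = {offs.pos_tpi183}\n"
            f"tpi_intron_start = {offs.tpi_intron_window[0]}\n"
            f"tpi_intron_end = {offs.tpi_intron_window[1]}\n"
        )
    print(f"wrote reference data to {OUT}")


if __name__ == "__main__":
    main()
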