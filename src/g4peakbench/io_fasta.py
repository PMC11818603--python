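"""FASTA convenience wrappers (pyfaidx-backed reading, plain writing)."""

from __future__ import annotations

from pathlib import Path

__all__ = ["load_fasta", "write_fasta"]


def load_fasta(path) -> dict[str, str]:
    """Load a (small) FASTA file fully into memory as {name: sequence}."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
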