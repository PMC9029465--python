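from pathlib import Path

import pytest

from hbskit.sequences import NucleotideSequence, write_fasta


@pytest.fixture
def fasta_file(tmp_path):
    """Write sequences (or raw text) to a temp FASTA file and return its path."""

    def _write(content, name="test.fa") -> Path:
        path = tmp_path / name
        if isinstance(content, str):
            path.write_text(content)
        else:
            write_fasta(content, path)
        return path

    return _write


@pytest.fixture
def pdb_file(tmp_path):
    def _write(text: str, name="test.pdb") -> Path:
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def make_sequence(residues: str, identifier: str = "seq") -> NucleotideSequence:
    return NucleotideSequence(identifier, residues)
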