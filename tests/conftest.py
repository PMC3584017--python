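import pytest

from barcodekit.io import LocusCollection, SequenceRecord


def make_collection(locus, entries):
    """entries: iterable of (sample_id, species, residues)."""
    return LocusCollection(
        locus,
        (SequenceRecord(sample_id=sid, species=sp, locus=locus, residues=seq)
         for sid, sp, seq in entries),
    )


@pytest.fixture
def toy_collection():
    """Three species, two genera; Beta is a singleton."""
    return make_collection("ITS", [
        ("A1", "Alpha one", "ACGTACGTACGT"),
        ("A2", "Alpha one", "ACGTACGTACGA"),
        ("B1", "Alpha two", "ACGTACGAACGA"),
        ("B2", "Alpha two", "ACGTACGAACGT"),
        ("C1", "Beta one", "TTTTACGAACGA"),
    ])


@pytest.fixture
def write_fasta_meta(tmp_path):
    """Write (sample_id, species, residues) entries as FASTA + metadata TSV."""

    def _write(entries, locus="ITS", name="test"):
        fasta = tmp_path / f"{name}.fasta"
        meta = tmp_path / f"{name}.tsv"
        with open(fasta, "w") as fh:
            for sid, _sp, seq in entries:
                fh.write(f">{sid}\n{seq}\n")
        with open(meta, "w") as fh:
            fh.write("sample_id\tspecies\tlocus\tsource\n")
            for sid, sp, _seq in entries:
                fh.write(f"{sid}\t{sp}\t{locus}\tstudy\n")
        return fasta, meta

    return _write
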