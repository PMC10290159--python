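"""Dataset container, paralog lumping and file I/O."""

import numpy as np
import pytest

import chronotox as ct
from chronotox.datasets import (ExpressionDataset, lump_paralogs,
                                read_expression, rescale_to_reference,
                                write_expression)


def _toy(genes, values, times=(0.0, 3.0)):
    return ExpressionDataset(genes, np.array(times), np.array(values))


def test_lump_sums_paralogs_elementwise():
    ds = _toy(["PER1", "PER2", "PER3"], [[1, 2], [3, 4], [0, 1]])
    out = lump_paralogs(ds, {"PER": ["PER1", "PER2", "PER3"]})
    assert out.genes == ["PER"]
    assert np.array_equal(out.series("PER"), [4, 7])


def test_lump_conserves_mass_and_passes_through():
    ds = _toy(["PER1", "PER2", "CES2"], [[1, 2], [3, 4], [5, 6]])
    out = lump_paralogs(ds, {"PER": ["PER1", "PER2"]})
    assert np.array_equal(out.series("PER"),
                          ds.series("PER1") + ds.series("PER2"))
    assert np.array_equal(out.series("CES2"), ds.series("CES2"))
    # total expression mass conserved per timepoint
    assert np.allclose(out.values.sum(axis=0), ds.values.sum(axis=0))


def test_identity_mapping_is_noop():
    ds = _toy(["A", "B"], [[1, 2], [3, 4]])
    out = lump_paralogs(ds, {})
    assert out.genes == ds.genes
    assert np.array_equal(out.values, ds.values)


def test_lump_missing_paralog_requires_ko_flag():
    ds = _toy(["PER1", "PER3"], [[1, 2], [3, 4]])
    with pytest.raises(ValueError, match="PER2"):
        lump_paralogs(ds, {"PER": ["PER1", "PER2", "PER3"]})
    out = lump_paralogs(ds, {"PER": ["PER1", "PER2", "PER3"]},
                        knocked_out=("PER2",))
    assert np.array_equal(out.series("PER"), [4, 6])


def test_paralog_in_two_lumps_rejected():
    ds = _toy(["A", "B"], [[1, 2], [3, 4]])
    with pytest.raises(ValueError, match="appears in both"):
        lump_paralogs(ds, {"X": ["A"], "Y": ["A", "B"]})


@pytest.mark.parametrize("bad,match", [
    (dict(genes=["A", "A"], values=[[1, 2], [3, 4]]), "duplicate"),
    (dict(genes=["A"], values=[[1, -2]]), "non-negative"),
    (dict(genes=["A"], values=[[1, np.nan]]), "finite"),
])
def test_dataset_validation(bad, match):
    with pytest.raises(ValueError, match=match):
        ExpressionDataset(times=np.array([0.0, 3.0]), **bad)


def test_unsorted_times_rejected():
    with pytest.raises(ValueError, match="increasing"):
        ExpressionDataset(["A"], np.array([3.0, 0.0]), np.array([[1, 2]]))


@pytest.mark.parametrize("fmt", ["tsv", "csv"])
def test_io_round_trip(tmp_path, fmt):
    ds = _toy(["GENE1", "GENE2"], [[1.25, 2.5], [0.0, 7.125]])
    path = tmp_path / f"expr.{fmt}"
    write_expression(ds, path, fmt=fmt)
    back = read_expression(path, fmt=fmt)
    assert back.genes == ds.genes
    assert np.allclose(back.times, ds.times, atol=1e-12)
    assert np.allclose(back.values, ds.values, atol=1e-12)


def test_read_rejects_duplicate_gene(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("gene\t0\t3\nA\t1\t2\nA\t3\t4\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_expression(path)


def test_read_rejects_na(tmp_path):
    path = tmp_path / "na.tsv"
    path.write_text("gene\t0\t3\nA\t1\t\n")
    with pytest.raises(ValueError, match="NA"):
        read_expression(path)


def test_rescale_identity_and_factor():
    ds = _toy(["A"], [[1.0, 3.0]])
    ref = _toy(["A"], [[3.0, 9.0]])
    assert np.array_equal(
        rescale_to_reference(ds, ds).values, ds.values)
    out = rescale_to_reference(ds, ref)
    assert np.allclose(out.series("A"), [3.0, 9.0])


def test_rescale_modes_differ_on_unequal_means():
    ds = _toy(["A", "B"], [[1.0, 1.0], [2.0, 2.0]])
    ref = _toy(["A", "B"], [[4.0, 4.0], [2.0, 2.0]])
    per_gene = rescale_to_reference(ds, ref, mode="per_gene")
    glob = rescale_to_reference(ds, ref, mode="global")
    # per-gene: A x4, B x1; global: both x2
    assert np.allclose(per_gene.series("A"), [4.0, 4.0])
    assert np.allclose(per_gene.series("B"), [2.0, 2.0])
    assert np.allclose(glob.series("A"), [2.0, 2.0])
    assert not np.allclose(per_gene.values, glob.values)
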