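import numpy as np
import pytest

from tsrnapipe import refmodel, simdata


@pytest.fixture(scope="session")
def refset():
    """Synthetic sncRNA reference with half + full-length features."""
    rs = simdata.example_reference(seed=2023)
    refmodel.build_half_annotations(rs)
    refmodel.build_full_length_features(rs)
    return rs


@pytest.fixture(scope="session")
def study_results(refset):
    """A 3 vs 3 simulated study at default conditions, fully analyzed."""
    from tsrnapipe import pipeline

    samples = pipeline.simulate_study(refset, seed=1, n_replicates=3, n_reads=20_000)
    return pipeline.analyze_samples(samples, refset)


@pytest.fixture(scope="session")
def tiny_refset():
    """Two tRNAs and one rRNA with known sequences, for hand-traceable tests."""
    rng = np.random.default_rng(7)
    rs = refmodel.ReferenceSet()
    bases = np.array(list("ACGT"))
    for ref_id, iso, length in [("tA", "Asp-GUC", 72), ("tB", "Lys-CUU", 70)]:
        seq = "".join(rng.choice(bases, size=length))
        rs.add_sequence(refmodel.ReferenceSequence(ref_id, "tRNA", seq))
        rs.add_annotation(refmodel.TRNAAnnotation(ref_id, iso, length, anticodon_start=33))
    rs.add_sequence(
        refmodel.ReferenceSequence("rX", "rRNA", "".join(rng.choice(bases, size=200)))
    )
    refmodel.build_half_annotations(rs)
    refmodel.build_full_length_features(rs)
    return rs
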