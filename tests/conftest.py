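import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pamcross.expression import MergedMatrix
from pamcross.simulate import PAM50_SUBTYPES, make_subtype_centroids

#: The package's standard synthetic study conditions.
BASE_PROBS = {"LumA": 0.35, "LumB": 0.20, "Her2": 0.10, "Basal": 0.15, "Normal": 0.20}


@pytest.fixture(scope="session")
def centroids():
    return make_subtype_centroids(42, PAM50_SUBTYPES, separation=2.0, seed=7)


def make_merged(values: np.ndarray, blocks: list[str], normalized=False) -> MergedMatrix:
    """Small helper: wrap a raw array as a MergedMatrix with given sample blocks."""
    n_g, n_s = values.shape
    genes = [f"G{i + 1:03d}" for i in range(n_g)]
    samples = [f"s{i + 1:03d}" for i in range(n_s)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return MergedMatrix(
        values=df,
        block_of_sample=pd.Series(blocks, index=samples),
        normalized=normalized,
    )


@pytest.fixture(scope="session")
def transfer_run(centroids):
    """The standard 60 reference + 60 query co-clustering run, fitted once.

    Returns (results, truth, merged, reference_labels).
    """
    from pamcross.expression import merge_matrices, normalize_unitization
    from pamcross.simulate import generate_backcross_genotypes, generate_query_cohort, PlantedLocus
    from pamcross.simulate import generate_reference_cohort
    from pamcross.transfer import SubtypeTransfer

    reference = generate_reference_cohort(centroids, 12, noise_sd=1.0, platform_id="ref", seed=11)
    genotypes = generate_backcross_genotypes(60, 500, seed=12)
    locus = PlantedLocus(marker_index=249, target_subtype="Basal", effect=0.4)
    query = generate_query_cohort(
        genotypes, [locus], centroids, BASE_PROBS,
        platform_shift=(2.0, 1.5), noise_sd=1.0, platform_id="query", seed=13,
    )
    merged = normalize_unitization(
        merge_matrices([reference.expression, query.expression])
    )
    model = SubtypeTransfer(merged, reference.true_labels)
    return model.fit(), query.true_labels, merged, reference.true_labels
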