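import pytest

from comorbidlink import ConditionalProbability, PopulationRates, RegulatoryEdge

# Study conditions for the diabetes / head-and-neck-cancer analysis:
# 10M-person synthetic population per sex, diabetes prevalence 6.9%,
# sex-specific cancer incidence, and cohort diabetic proportions.


@pytest.fixture
def rates_by_sex() -> dict[str, PopulationRates]:
    return {
        "male": PopulationRates(0.069, 0.000152, 10_000_000),
        "female": PopulationRates(0.069, 0.0000761, 10_000_000),
    }


@pytest.fixture
def probs_by_sex() -> dict[str, ConditionalProbability]:
    return {
        "male": ConditionalProbability("male", 127, 692),
        "female": ConditionalProbability("female", 5, 36),
    }


@pytest.fixture
def dm_edges() -> list[RegulatoryEdge]:
    """Signed diabetes->gene regulation claims for the four core genes."""
    return [
        RegulatoryEdge("DM", "APP", "positive", 4, 0.00015),
        RegulatoryEdge("DM", "NLRP3", "positive", 19, 0.00168),
        RegulatoryEdge("DM", "PVT1", "positive", 4, 0.00755),
        RegulatoryEdge("DM", "CYP2C19", "negative", 14, 0.00372),
    ]


@pytest.fixture
def hnscc_edges() -> list[RegulatoryEdge]:
    return [
        RegulatoryEdge("HNSCC", "APP", "positive", 4, 0.00832),
        RegulatoryEdge("HNSCC", "NLRP3", "positive", 5, 0.00229),
        RegulatoryEdge("HNSCC", "PVT1", "positive", 8, 0.00229),
        RegulatoryEdge("HNSCC", "CYP2C19", "negative", 4, 0.00832),
    ]
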