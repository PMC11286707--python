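import math

import pytest

from mrf import MrfCatalog, packaged_catalog


@pytest.fixture(scope="session")
def catalog() -> MrfCatalog:
    return packaged_catalog()


def make_catalog(class_specs, version="test", provenance="test fixture"):
    """Build a small in-memory catalog from (class_id, tier, members) tuples."""
    return MrfCatalog.model_validate({
        "version": version,
        "provenance": provenance,
        "classes": [
            {
                "class_id": cid,
                "name": cid.replace("_", " "),
                "tier": tier,
                "mechanism": "test mechanism",
                "members": list(members),
                "synonyms": dict(synonyms or {}),
            }
            for cid, tier, members, *rest in class_specs
            for synonyms in [rest[0] if rest else None]
        ],
    })


@pytest.fixture
def toy_catalog() -> MrfCatalog:
    """Three single-tier classes plus one drug shared between two tiers."""
    return make_catalog([
        ("sedatives", "high", ["drowsinol", "sharedrug"]),
        ("pressors", "moderate", ["dizzipril", "sharedrug"],
         {"dizzipril xl": "dizzipril"}),
        ("mildones", "low", ["gentlin"]),
    ])


def oracle_quartile(values, p):
    """Independent weighted-average quantile at position (n+1)p, by hand."""
    s = sorted(values)
    n = len(s)
    h = (n + 1) * p
    k = math.floor(h)
    g = h - k
    if k < 1:
        return float(s[0])
    if k >= n:
        return float(s[-1])
    return s[k - 1] + g * (s[k] - s[k - 1])


def oracle_median(values):
    s = sorted(values)
    n = len(s)
    mid = n // 2
    if n % 2:
        return float(s[mid])
    return (s[mid - 1] + s[mid]) / 2.0


def oracle_verdict(values, final_round):
    """Brute-force restatement of the consensus rules, independent of numpy."""
    m = oracle_median(values)
    p25 = oracle_quartile(values, 0.25)
    if m >= 4 and p25 >= 4:
        return "retain"
    if m <= 3:
        return "exclude"
    return "exclude" if final_round else "modify"
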