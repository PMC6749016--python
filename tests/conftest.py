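import numpy as np
import pytest

from varconcord.callset import (
    CallSet,
    FusionCall,
    Platform,
    VariantCall,
    normalize_variant_key,
)

GENES = ["BRAF", "NRAS", "HRAS", "KRAS", "TSHR", "SPOP", "EIF1AX", "GNAS"]
CHANGES = ["V600E", "Q61R", "Q61K", "M453T", "P94R", "G8R", "Q870H", "G13R"]


def random_variant_callset(
    rng: np.random.Generator,
    platform: Platform = Platform.WTS_RNASEQ,
    n_samples: int = 8,
    n_calls: int = 12,
) -> CallSet:
    """Small random call set for oracle-equivalence tests."""
    calls = []
    seen = set()
    for _ in range(n_calls):
        sample = f"S{rng.integers(n_samples):02d}"
        key = normalize_variant_key(
            GENES[rng.integers(len(GENES))], CHANGES[rng.integers(len(CHANGES))]
        )
        if (sample, key) in seen:
            continue
        seen.add((sample, key))
        total = int(rng.integers(50, 500))
        alt = int(rng.integers(0, total + 1))
        calls.append(
            VariantCall(
                sample_id=sample, key=key, vaf=alt / total,
                alt_depth=alt, total_depth=total, platform=platform,
            )
        )
    return CallSet(platform=platform, variant_calls=calls)


def make_variant_call(
    sample="S1", gene="BRAF", change="V600E", vaf=0.3,
    platform=Platform.WTS_RNASEQ, total=100,
):
    alt = round(vaf * total)
    return VariantCall(
        sample_id=sample,
        key=normalize_variant_key(gene, change),
        vaf=alt / total,
        alt_depth=alt,
        total_depth=total,
        platform=platform,
    )


def make_fusion_call(sample="S1", p5="CCDC6", p3="RET", platform=Platform.WTS_RNASEQ):
    return FusionCall(
        sample_id=sample, partner5=p5, partner3=p3,
        supporting_reads=40, total_valid_mapped_reads=40000, platform=platform,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
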