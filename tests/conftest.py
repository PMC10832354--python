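import random

import pytest

from anchorlift import build_index, lift_record
from anchorlift.annotation_update import TagRules
from anchorlift.lift_engine import LiftOptions
from anchorlift.synthetic_fixtures import (
    FIXTURE_FORMAT_NUMBERS,
    FIXTURE_INFO_NUMBERS,
    generate_pair,
)
from anchorlift.variant_model import InMemoryGenome, VariantRecord


@pytest.fixture(scope="session")
def fixture_rules():
    return TagRules(info_numbers=FIXTURE_INFO_NUMBERS,
                    format_numbers=FIXTURE_FORMAT_NUMBERS)


@pytest.fixture(scope="session")
def pair_gap():
    """Small assembly pair with gap-style (BLAT-like) chains."""
    return generate_pair(seed=7, contig_length=20_000, n_variants=80,
                         chain_style="gap")


@pytest.fixture(scope="session")
def pair_tolerant():
    """Same scenario mix with mismatch-tolerant chains."""
    return generate_pair(seed=7, contig_length=20_000, n_variants=80,
                         chain_style="tolerant")


def lift_all(pair, rules, opts=None):
    """Lift every planted record of a pair; results keyed like the truth."""
    opts = opts or LiftOptions()
    index = build_index(pair.chains())
    src, dst = pair.src_genome, pair.dst_genome
    return {t.key: lift_record(t.record, index, src, dst, opts, rules)
            for t in pair.truth}


@pytest.fixture(scope="session")
def str_genome():
    """14 bp contig with a CA repeat: GGG(CA)x3+C A GGG layout used in the
    worked normalization/extension examples."""
    return InMemoryGenome({"c": "GGGCACACACAGGG"})


@pytest.fixture()
def rng():
    return random.Random(20240901)


def make_record(contig, pos, ref, alts, **kw):
    return VariantRecord(contig=contig, pos=pos, ref=ref,
                         alts=tuple(alts) if isinstance(alts, (list, tuple)) else (alts,),
                         **kw)
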