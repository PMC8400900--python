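import pytest

import nutriwarn as nw
from nutriwarn.records import Basis, PerUnit


@pytest.fixture(scope="session")
def taxonomy():
    return nw.Taxonomy.default()


@pytest.fixture(scope="session")
def searo_table():
    return nw.ThresholdTable.default_searo()


@pytest.fixture(scope="session")
def cwo_table():
    return nw.ThresholdTable.default_cwo_phase3()


def make_record(
    category_code="1",
    barcode="B001",
    flags=None,
    basis=Basis.AS_CONSUMED,
    per=PerUnit.PER_100G,
    dilution_factor=None,
    **amounts,
):
    """Terse record builder: nutrient amounts as keyword args, absent by default."""
    return nw.ProductRecord(
        barcode=barcode,
        name=f"test-{barcode}",
        category_code=category_code,
        panel=nw.NutrientPanel(basis=basis, per=per, **amounts),
        flags=flags or nw.IngredientFlags(),
        dilution_factor=dilution_factor,
    )


def zero_panel_record(category_code="1", barcode="B001", flags=None):
    return make_record(
        category_code=category_code,
        barcode=barcode,
        flags=flags,
        energy=0.0,
        total_fat=0.0,
        saturated_fat=0.0,
        total_sugar=0.0,
        added_sugar=0.0,
        sodium=0.0,
    )
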