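"""Published reference association table (packaged fixture).

A transcription of a published torus-translation association table for 57
woody-plant species (37 trees, 20 shrubs) censused in four 1-ha plots of a
temperate deciduous broad-leaved forest under four disturbance regimes:

    A = plantation forest      (high disturbance)
    B = twice-cut forest       (moderate disturbance)
    C = once-cut forest        (slight disturbance)
    D = old-growth forest      (undisturbed)

Each species carries its significant associations (P <= 0.05, two-tailed)
as ``community(sign)`` tokens, or ``NA`` for none.  The raw census behind
the table is not public; this table is the ground truth against which the
reporting/summary logic is exercised.
"""

from __future__ import annotations

import io
import re

import pandas as pd

__all__ = ["load_reference_associations", "reference_long_table", "COMMUNITIES"]

COMMUNITIES = {
    "A": "plantation",
    "B": "twice-cut",
    "C": "once-cut",
    "D": "old-growth",
}

# species \t life form \t associations
_TABLE = """\
Betula platyphylla\ttree\tB(+) D(-)
Fraxinus chinensis\ttree\tD(+)
Symplocos paniculata\tshrub\tB(+) D(-)
Ailanthus altissima\ttree\tD(+)
Cornus controversa\ttree\tNA
Quercus serrata var. brevipetiolata\ttree\tNA
Carpinus turczaninowii\ttree\tC(+) D(-)
Acer davidii subsp. grosseri\ttree\tNA
Alangium platanifolium\tshrub\tD(+)
Malus honanensis\tshrub\tC(-) D(+)
Malus hupehensis\ttree\tNA
Sorbus hupehensis\tshrub\tD(+)
Lonicera tatarinowii\tshrub\tNA
Tilia japonica\ttree\tNA
Pinus armandii\ttree\tC(+)
Corylus chinensis\ttree\tNA
Crataegus wilsonii\tshrub\tNA
Viburnum betulifolium\tshrub\tB(+)
Cotoneaster acutifolius\tshrub\tD(+)
Viburnum opulus var. sargentii\tshrub\tNA
Betula chinensis\ttree\tNA
Sambucus williamsii\tshrub\tD(+)
Cornus macrophylla\ttree\tNA
Forsythia suspensa\tshrub\tC(+)
Betula luminifera\ttree\tNA
Euptelea pleiosperma\ttree\tNA
Abelia biflora\tshrub\tD(+)
Larix gmelinii\ttree\tNA
Cornus walteri\ttree\tA(+)
Celastrus orbiculatus\tshrub\tNA
Meliosma veitchiorum\ttree\tD(-)
Toxicodendron vernicifluum\ttree\tA(+) D(-)
Carpinus cordata\ttree\tD(-)
Litsea tsinlingensis\ttree\tD(+)
Berberis circumserrata\tshrub\tD(+)
Acer davidii\ttree\tNA
Quercus aliena var. acutiserrata\ttree\tC(-)
Lindera obtusiloba\ttree\tNA
Philadelphus incanus\tshrub\tD(+)
Populus davidiana\ttree\tD(+)
Cerasus serrulata\ttree\tNA
Tilia paucicostata\ttree\tC(+)
Salix shihtsuanensis\tshrub\tNA
Euonymus phellomanus\tshrub\tD(+)
Quercus variabilis\ttree\tNA
Sorbus alnifolia\ttree\tNA
Cornus kousa subsp. chinensis\tshrub\tB(+) D(-)
Cerasus clarofolia\tshrub\tB(-)
Acer pictum subsp. mono\ttree\tB(-) D(+)
Salix chaenomeloides\ttree\tD(+)
Juglans cathayensis\ttree\tNA
Pinus tabuliformis\ttree\tB(-)
Yulania denudata\ttree\tNA
Styrax obassis\ttree\tNA
Acer truncatum\ttree\tNA
Rhododendron micranthum\tshrub\tNA
Corylus heterophylla\ttree\tB(+)
"""

_TOKEN = re.compile(r"^([A-D])\(([+-])\)$")


def load_reference_associations() -> pd.DataFrame:
    """The reference table in wide form: species, life_form, associations."""
    df = pd.read_csv(
        io.StringIO(_TABLE),
        sep="\t",
        names=["species", "life_form", "associations"],
        keep_default_na=False,
    )
    return df


def reference_long_table(alpha: float = 0.05) -> pd.DataFrame:
    """The reference table as an association table (one row per pair).

    Expands each ``community(sign)`` token into a row with columns
    ``species, life_form, habitat, class``; species with no association
    contribute a single row with habitat NA and class ``none`` so that
    species-level counts remain recoverable.  (Observed relative densities
    and p-values are not published; those columns are absent.)
    """
    rows = []
    for rec in load_reference_associations().itertuples():
        tokens = rec.associations.split()
        if tokens == ["NA"]:
            rows.append(
                {
                    "species": rec.species,
                    "life_form": rec.life_form,
                    "habitat": None,
                    "class": "none",
                }
            )
            continue
        for tok in tokens:
            m = _TOKEN.match(tok)
            if not m:
                raise ValueError(f"malformed association token {tok!r}")
            rows.append(
                {
                    "species": rec.species,
                    "life_form": rec.life_form,
                    "habitat": m.group(1),
                    "class": "positive" if m.group(2) == "+" else "negative",
                }
            )
    return pd.DataFrame(rows)
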