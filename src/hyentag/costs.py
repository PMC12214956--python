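"""Per-tag write-and-read cost calculator.

The cost of one tag plus one (destructive) ticket readout is linear in the
bit count: fixed costs for the nitrocellulose ticket and buffer/ink, plus a
per-bit taggant and reporter oligo cost.  Defaults reflect list prices for
synthesized oligos at the amounts consumed per bit (240 pmol of taggant,
0.5 pmol of spotted reporter), giving $0.3524 for a 1-bit tag and $2.774
for a full 25-bit ticket.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CostTable", "tag_cost"]


@dataclass(frozen=True)
class CostTable:
    """Unit costs (USD) and DNA amounts (pmol) per write-and-read."""

    taggant_cost_per_bit: float = 0.1
    reporter_cost_per_bit: float = 0.0009
    paper_cost_per_ticket: float = 0.25
    buffer_ink_cost: float = 0.0015
    taggant_pmol_per_bit: float = 240.0
    reporter_pmol_per_bit: float = 0.5

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def tag_cost(n_bits: int, table: CostTable | None = None) -> dict[str, float]:
    """Itemized cost of writing and reading one n-bit tag.

    total = paper + buffer/ink + n_bits * (taggant + reporter)
    """
    if n_bits < 0:
        raise ValueError("n_bits must be >= 0")
    if table is None:
        table = CostTable()
    taggant = n_bits * table.taggant_cost_per_bit
    reporter = n_bits * table.reporter_cost_per_bit
    return {
        "n_bits": n_bits,
        "taggant_cost": taggant,
        "reporter_cost": reporter,
        "paper_cost": table.paper_cost_per_ticket,
        "buffer_ink_cost": table.buffer_ink_cost,
        "taggant_pmol": n_bits * table.taggant_pmol_per_bit,
        "reporter_pmol": n_bits * table.reporter_pmol_per_bit,
        "total": taggant + reporter + table.paper_cost_per_ticket + table.buffer_ink_cost,
    }
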