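"""Validation modes emulating the capabilities of each conceptual schema.

The species-independent schema (CSG) accepts every write the instance model
supports.  The two species-specific schemas it generalizes are narrower, and
emulating them turns their documented blind spots into
:class:`~genoschema.errors.CapabilityError`:

* CSHG — no individual level in the variation view, and genotype
  frequencies only for SNPs;
* CSCG — no population level, no bibliography/databank view, and a single
  working assembly.
"""

from enum import Enum


class SchemaMode(str, Enum):
    CSG = "CSG"
    CSHG = "CSHG"
    CSCG = "CSCG"
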