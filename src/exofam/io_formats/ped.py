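"""Standard 6-column PED pedigree reader/writer.

Columns: family_id, sample_id, father_id, mother_id, sex, phenotype.
Sex codes 1/2 map to male/female; phenotype 2 -> affected, 1 -> unaffected,
0 or -9 -> unknown.  A parent id of ``0`` marks a founder.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

from .models import Affection, FormatError, Pedigree, SampleInfo, Sex

log = logging.getLogger(__name__)

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_PHENO_CODES = {
    "2": Affection.AFFECTED,
    "1": Affection.UNAFFECTED,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2"}
_PHENO_OUT = {
    Affection.AFFECTED: "2",
    Affection.UNAFFECTED: "1",
    Affection.UNKNOWN: "0",
}


def read_ped(path: Union[str, Path]) -> Pedigree:
    """Parse a PED file into a validated :class:`Pedigree`.

    Raises :class:`FormatError` for malformed rows, duplicate sample ids,
    unknown sex/phenotype codes, or parent ids absent from the file.
    """
    path = Path(path)
    samples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            _fam, sid, father, mother, sex_code, pheno_code = fields
            if sex_code not in _SEX_CODES:
                raise FormatError(
                    f"{path}:{lineno}: unknown sex code {sex_code!r} "
                    f"for sample {sid!r}"
                )
            if pheno_code not in _PHENO_CODES:
                raise FormatError(
                    f"{path}:{lineno}: unknown phenotype code {pheno_code!r} "
                    f"for sample {sid!r}"
                )
            samples.append(
                SampleInfo(
                    sample_id=sid,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=_SEX_CODES[sex_code],
                    affected=_PHENO_CODES[pheno_code],
                )
            )
    if not samples:
        log.warning("PED file %s is empty", path)
        return Pedigree([])
    return Pedigree(samples)


def write_ped(
    pedigree: Pedigree, path: Union[str, Path], family_id: str = "FAM1"
) -> None:
    """Write a pedigree back to 6-column PED, one row per sample."""
    with open(path, "w") as fh:
        for s in pedigree:
            fh.write(
                "\t".join(
                    [
                        family_id,
                        s.sample_id,
                        s.father_id or "0",
                        s.mother_id or "0",
                        _SEX_OUT[s.sex],
                        _PHENO_OUT[s.affected],
                    ]
                )
                + "\n"
            )
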