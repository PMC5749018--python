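"""FISH probe panel definitions.

A panel is a set of probes assembled into multicolour hybridisation mixes.
Three probe classes are distinguished:

``locus``
    single-locus copy-number probe (gain / loss / homozygous-deletion scoring),
    optionally paired with a same-chromosome centromeric control for ratio
    scoring;
``centromere_control``
    centromere-enumeration (CEP) probe used as the ploidy control for locus
    probes on the same chromosome;
``break_apart``
    two-colour probe flanking a gene; colocalised (fusion) signals mean an
    intact locus, separated red/green signals a rearrangement.

The default panel targets recurrent prostate-cancer lesions in three mixes:
mix 1 {PTEN, CEP10, ERG break-apart}, mix 2 {NKX3.1, CEP8, FGFR1, MYC},
mix 3 {CDKN1B, NMYC, ETV1 break-apart}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ValidationError

PROBE_CLASSES = ("locus", "centromere_control", "break_apart")
CUTOFF_CLASSES = ("amplification", "deletion", "break_apart", "none")

#: scorable parameter kinds by cut-off class (the probe's lesion class)
AMPLIFICATION_PARAMS = ("Gain",)
DELETION_PARAMS = ("Loss", "Homozygous")
BREAK_APART_PARAMS = ("Split", "2Edel")


@dataclass(frozen=True)
class ProbeDef:
    """One FISH probe in a hybridisation mix.

    Parameters
    ----------
    probe_id :
        Short unique name, e.g. ``PTEN`` or ``ERG_BA``.
    probe_class :
        One of ``locus``, ``centromere_control``, ``break_apart``.
    mix_id :
        Hybridisation mix the probe belongs to (1-3).
    control_probe_id :
        ``probe_id`` of the same-chromosome centromeric control used for the
        Ratio parameter, or ``None``.
    cutoff_class :
        Cut-off search range class: ``amplification``, ``deletion``,
        ``break_apart`` or ``none`` (controls only).
    scores_2edel :
        Whether the 2Edel rearrangement-with-deletion pattern is scored for
        this break-apart probe (ERG only in the default panel).
    """

    probe_id: str
    probe_class: str
    mix_id: int
    control_probe_id: str | None = None
    cutoff_class: str = "none"
    scores_2edel: bool = False

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise ValidationError(
                f"probe {self.probe_id}: unknown probe_class {self.probe_class!r}"
            )
        if self.cutoff_class not in CUTOFF_CLASSES:
            raise ValidationError(
                f"probe {self.probe_id}: unknown cutoff_class {self.cutoff_class!r}"
            )
        if self.cutoff_class == "none" and self.probe_class != "centromere_control":
            raise ValidationError(
                f"probe {self.probe_id}: cutoff_class 'none' is reserved for "
                "centromere_control probes"
            )
        if self.probe_class == "centromere_control" and self.cutoff_class != "none":
            raise ValidationError(
                f"probe {self.probe_id}: centromere controls take cutoff_class 'none'"
            )
        if self.scores_2edel and self.probe_class != "break_apart":
            raise ValidationError(
                f"probe {self.probe_id}: 2Edel is only scored for break-apart probes"
            )

    @property
    def display_name(self) -> str:
        """Gene name used in parameter labels (``ERG_BA`` -> ``ERG``)."""
        return self.probe_id.removesuffix("_BA")

    def parameter_names(self) -> list[str]:
        """Specimen-level parameters scored for this probe, in report order.

        Parameters follow the probe's lesion class: amplification probes are
        scored for Gain, deletion probes for Loss and Homozygous, break-apart
        probes for Split (and 2Edel where applicable); locus probes with a
        same-chromosome centromeric control additionally get Ratio.
        """
        if self.probe_class == "locus":
            kinds = AMPLIFICATION_PARAMS if self.cutoff_class == "amplification" else DELETION_PARAMS
            names = [f"{self.display_name} {p}" for p in kinds]
            if self.control_probe_id is not None:
                names.append(f"{self.display_name} Ratio")
            return names
        if self.probe_class == "break_apart":
            names = [f"{self.display_name} Split"]
            if self.scores_2edel:
                names.append(f"{self.display_name} 2Edel")
            return names
        return []  # centromere controls carry no parameters of their own


@dataclass
class ProbePanel:
    """An ordered collection of :class:`ProbeDef` with cross-reference checks."""

    probes: list[ProbeDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate probe_id in panel")
        by_id = {p.probe_id: p for p in self.probes}
        for p in self.probes:
            if p.control_probe_id is None:
                continue
            ctrl = by_id.get(p.control_probe_id)
            if ctrl is None:
                raise ValidationError(
                    f"probe {p.probe_id}: control {p.control_probe_id} not in panel"
                )
            if ctrl.probe_class != "centromere_control" or ctrl.mix_id != p.mix_id:
                raise ValidationError(
                    f"probe {p.probe_id}: control {p.control_probe_id} must be a "
                    "centromere_control probe in the same mix"
                )

    def __iter__(self):
        return iter(self.probes)

    def __len__(self) -> int:
        return len(self.probes)

    def __getitem__(self, probe_id: str) -> ProbeDef:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    @property
    def mix_ids(self) -> list[int]:
        return sorted({p.mix_id for p in self.probes})

    def in_mix(self, mix_id: int) -> list[ProbeDef]:
        return [p for p in self.probes if p.mix_id == mix_id]

    def parameter_names(self) -> list[str]:
        """All scored parameter names, ordered by mix then panel order."""
        out: list[str] = []
        for p in self.probes:
            out.extend(p.parameter_names())
        return out

    def probe_for_parameter(self, parameter_name: str) -> ProbeDef:
        """Map a parameter label like ``'MYC Gain'`` back to its probe."""
        display = parameter_name.rsplit(" ", 1)[0]
        for p in self.probes:
            if p.display_name == display:
                return p
        raise KeyError(f"no probe for parameter {parameter_name!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": [p.probe_id for p in self.probes],
                "probe_class": [p.probe_class for p in self.probes],
                "mix_id": [p.mix_id for p in self.probes],
                "control_probe_id": [p.control_probe_id or "" for p in self.probes],
                "cutoff_class": [p.cutoff_class for p in self.probes],
                "scores_2edel": [int(p.scores_2edel) for p in self.probes],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbePanel":
        probes = [
            ProbeDef(
                probe_id=str(r.probe_id),
                probe_class=str(r.probe_class),
                mix_id=int(r.mix_id),
                control_probe_id=(str(r.control_probe_id) or None)
                if not pd.isna(r.control_probe_id) and str(r.control_probe_id) != ""
                else None,
                cutoff_class=str(r.cutoff_class),
                scores_2edel=bool(int(getattr(r, "scores_2edel", 0) or 0)),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(probes)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ProbePanel":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def default_panel() -> ProbePanel:
    """The ten-probe, three-mix prostate panel used throughout the pipeline."""
    return ProbePanel(
        [
            ProbeDef("PTEN", "locus", 1, control_probe_id="CEP10", cutoff_class="deletion"),
            ProbeDef("CEP10", "centromere_control", 1),
            ProbeDef("ERG_BA", "break_apart", 1, cutoff_class="break_apart", scores_2edel=True),
            ProbeDef("NKX3.1", "locus", 2, control_probe_id="CEP8", cutoff_class="deletion"),
            ProbeDef("CEP8", "centromere_control", 2),
            ProbeDef("FGFR1", "locus", 2, cutoff_class="amplification"),
            ProbeDef("MYC", "locus", 2, control_probe_id="CEP8", cutoff_class="amplification"),
            ProbeDef("CDKN1B", "locus", 3, cutoff_class="deletion"),
            ProbeDef("NMYC", "locus", 3, cutoff_class="amplification"),
            ProbeDef("ETV1_BA", "break_apart", 3, cutoff_class="break_apart"),
        ]
    )


#: the seven candidate parameters carried into combination search
CANDIDATE_PARAMETERS = (
    "PTEN Homozygous",
    "MYC Gain",
    "FGFR1 Gain",
    "NMYC Gain",
    "ETV1 Split",
    "PTEN Loss",
    "ERG 2Edel",
)
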