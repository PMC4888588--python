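"""Run configuration: a flat key=value file, every field overridable."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class RunConfig:
    """All pipeline knobs with their defaults.

    Paths may be None when a stage is skipped (no blacklist, no FASTA).
    ``ploidy`` maps chromosome name -> baseline copy number for entries
    that deviate from disomy (e.g. allosomes of a male sample).
    """

    # paths
    alignments_dir: str | None = None
    chrom_sizes: str | None = None
    mappability: str = "uniform"      # bedGraph/BigWig/BAM path or "uniform"
    blacklist: str | None = None
    fasta: str | None = None
    output_dir: str = "karyoscope_out"
    # binning
    target_width: int = 1_000_000
    # HMM
    c_max: int = 10
    most_frequent_state: int = 2
    tol: float = 1e-4
    max_iter: int = 200
    n_restarts: int = 3
    seed: int = 0
    # QC / counting
    min_mapq: int = 10
    discard_duplicates: bool = True
    k_max: int = 3
    # scoring
    ploidy: dict = field(default_factory=dict)

    _BOOLS = {"discard_duplicates"}
    _INTS = {"target_width", "c_max", "most_frequent_state", "max_iter",
             "n_restarts", "seed", "min_mapq", "k_max"}
    _FLOATS = {"tol"}

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                if f.name == "ploidy":
                    val = ",".join(f"{k}:{v}" for k, v in self.ploidy.items())
                else:
                    val = getattr(self, f.name)
                fh.write(f"{f.name}={'' if val is None else val}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = cls()
        valid = {f.name for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, _, raw = line.partition("=")
                key = key.strip()
                raw = raw.strip()
                if key not in valid:
                    raise ValueError(f"unknown config key {key!r}")
                cfg._set(key, raw)
        return cfg

    def _set(self, key: str, raw: str) -> None:
        if key == "ploidy":
            val = {}
            for item in filter(None, raw.split(",")):
                chrom, _, p = item.partition(":")
                val[chrom.strip()] = int(p)
        elif raw == "":
            val = None
        elif key in self._BOOLS:
            val = raw.lower() in ("1", "true", "yes", "on")
        elif key in self._INTS:
            val = int(raw)
        elif key in self._FLOATS:
            val = float(raw)
        else:
            val = raw
        setattr(self, key, val)

    def override(self, **kwargs) -> "RunConfig":
        for key, val in kwargs.items():
            if val is not None:
                setattr(self, key, val)
        return self
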