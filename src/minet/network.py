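"""N-Net / MSN-Net architecture descriptions.

The network processes each of the 12 leads in an independent branch.  Within
a branch, scale path ``s`` (s = 1..S) first applies (s-1) learnable pooling
convolutions (kernel size = stride = pooling factor), then two unpadded
kernel-3, stride-1 convolutions, then global average pooling over time,
yielding F features.  All 12 x S x F features are concatenated, passed
through dropout (rate 0.5) and a softmax fully-connected layer of C units.
S = 1 is the single-scale N-Net; S > 1 is the multi-scale MSN-Net.

All convolutions use ReLU; convolutions are valid (unpadded), so each
kernel-3 layer shortens the temporal axis by exactly 2.  No batch
normalization is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ModelConfig:
    num_scales: int
    num_filters: int
    num_classes: int
    input_length: int = 400
    num_leads: int = 12
    dropout_rate: float = 0.5
    pooling_factor: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.num_scales:
            raise ValueError("num_scales must be >= 1")
        if self.num_filters < 1:
            raise ValueError("num_filters must be >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.pooling_factor < 2:
            raise ValueError("pooling_factor must be >= 2")
        for s in range(1, self.num_scales + 1):
            if self._pooled_length(s) <= 2 + 2:
                raise ValueError(
                    f"scale {s}: length {self._pooled_length(s)} after pooling "
                    "leaves no room for two kernel-3 convolutions"
                )

    def _pooled_length(self, scale: int) -> int:
        length = self.input_length
        for _ in range(scale - 1):
            length = (length - self.pooling_factor) // self.pooling_factor + 1
        return length

    @property
    def name(self) -> str:
        kind = "N-Net" if self.num_scales == 1 else "MSN-Net"
        return f"{kind}(S={self.num_scales}, F={self.num_filters}, C={self.num_classes})"

    @property
    def feature_width(self) -> int:
        return self.num_leads * self.num_scales * self.num_filters


@dataclass(frozen=True)
class LayerDesc:
    kind: str          # "conv", "gap", "dropout", "dense"
    kernel: int = 0
    stride: int = 1
    filters: int = 0
    in_channels: int = 0
    padding: str = "valid"
    activation: str = "relu"
    out_length: int = 0

    @property
    def n_parameters(self) -> int:
        if self.kind == "conv":
            return (self.kernel * self.in_channels + 1) * self.filters
        if self.kind == "dense":
            return (self.in_channels + 1) * self.filters
        return 0


@dataclass
class ModelSpec:
    """Layer-by-layer description of one configuration's computation graph.

    ``scale_paths[s]`` lists the layers of scale path s+1, applied per lead
    branch (weights are independent across the 12 leads and across paths).
    """

    config: ModelConfig
    scale_paths: list[list[LayerDesc]] = field(default_factory=list)
    head: list[LayerDesc] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        per_lead = sum(l.n_parameters for path in self.scale_paths for l in path)
        head = sum(l.n_parameters for l in self.head)
        return self.config.num_leads * per_lead + head

    def layer_table(self) -> str:
        """Human-readable layer summary."""
        lines = [f"{self.config.name}  ({self.n_parameters} trainable parameters)"]
        for s, path in enumerate(self.scale_paths, start=1):
            lines.append(f"  scale {s} (x{self.config.num_leads} lead branches):")
            for l in path:
                if l.kind == "conv":
                    lines.append(
                        f"    conv K={l.kernel} stride={l.stride} filters={l.filters} "
                        f"{l.padding} {l.activation} -> length {l.out_length}"
                    )
                else:
                    lines.append(f"    {l.kind}")
        lines.append(f"  concatenate -> {self.config.feature_width} features")
        for l in self.head:
            if l.kind == "dense":
                lines.append(f"  dense units={l.filters} activation={l.activation}")
            else:
                lines.append(f"  {l.kind}(rate={self.config.dropout_rate})")
        return "\n".join(lines)


def build_model_spec(config: ModelConfig) -> ModelSpec:
    """Derive the full layer plan for one (S, F, C) configuration."""
    F, P = config.num_filters, config.pooling_factor
    paths: list[list[LayerDesc]] = []
    for s in range(1, config.num_scales + 1):
        path: list[LayerDesc] = []
        length = config.input_length
        cin = 1
        for _ in range(s - 1):  # learnable pooling stages
            length = (length - P) // P + 1
            path.append(LayerDesc("conv", kernel=P, stride=P, filters=F,
                                  in_channels=cin, out_length=length))
            cin = F
        for _ in range(2):      # feature extraction, each shortens by 2
            length -= 2
            if length < 1:
                raise ValueError(f"scale {s}: temporal length exhausted before GAP")
            path.append(LayerDesc("conv", kernel=3, stride=1, filters=F,
                                  in_channels=cin, out_length=length))
            cin = F
        path.append(LayerDesc("gap", out_length=1))
        paths.append(path)
    head = [
        LayerDesc("dropout"),
        LayerDesc("dense", in_channels=config.feature_width,
                  filters=config.num_classes, activation="softmax"),
    ]
    return ModelSpec(config=config, scale_paths=paths, head=head)


def count_parameters(config: ModelConfig) -> int:
    """Closed-form trainable-parameter count.

    Per lead: sum over scales s of (s-1) pooling convolutions of
    (P*cin + 1)*F plus two feature convolutions (3*cin + 1)*F and
    (3*F + 1)*F, with cin = 1 for the first convolution of each scale path
    and F thereafter.  Head: (12*S*F + 1)*C.
    """
    F, P, C = config.num_filters, config.pooling_factor, config.num_classes
    per_lead = 0
    for s in range(1, config.num_scales + 1):
        cin = 1
        for _ in range(s - 1):
            per_lead += (P * cin + 1) * F
            cin = F
        per_lead += (3 * cin + 1) * F
        per_lead += (3 * F + 1) * F
    head = (config.feature_width + 1) * C
    return config.num_leads * per_lead + head


GRID_SCALES = range(1, 6)
GRID_FILTERS_DETECTION = range(1, 11)
GRID_FILTERS_LOCATING_SINGLE_SCALE = range(1, 16)

TASK_CLASSES = {"detection": 2, "locating": 6}


def enumerate_grid(
    task: str,
    scales: tuple[int, ...] | None = None,
    filters: tuple[int, ...] | None = None,
    input_length: int = 400,
) -> list[ModelConfig]:
    """The (scales x filters) search grid, in deterministic S-major order.

    Detection: S in 1..5 x F in 1..10 (50 configurations).  Locating: the
    same plus single-scale F in 11..15 (55 configurations).  Custom
    ``scales``/``filters`` override the defaults.
    """
    if task not in TASK_CLASSES:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASK_CLASSES)}")
    C = TASK_CLASSES[task]
    configs = []
    for s in scales or GRID_SCALES:
        if filters is not None:
            f_range = filters
        elif task == "locating" and s == 1:
            f_range = GRID_FILTERS_LOCATING_SINGLE_SCALE
        else:
            f_range = GRID_FILTERS_DETECTION
        for f in f_range:
            configs.append(ModelConfig(num_scales=s, num_filters=f, num_classes=C,
                                       input_length=input_length))
    return configs
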