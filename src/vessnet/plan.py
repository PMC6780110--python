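"""Declarative architecture plan for the Vess-Net encoder-decoder.

Vess-Net is a 16-convolution-layer semantic segmentation network arranged as
four encoder blocks and four mirrored decoder blocks.  Two residual streams
run through it:

* an inner stream of six *projection* skip paths (IRSP-1..6): a 1x1
  convolution + batch norm that carries each block's input to the output of
  the block's second convolution, where the two are added elementwise;
* an outer stream of four *identity* skip paths (ORSP-1..4): the activation
  after the first ReLU of encoder block *i* is added, unchanged, after the
  first ReLU of the matching decoder block.

The first encoder block and the last decoder block carry no inner projection.
Downsampling is 2x2 max pooling with stored argmax indices; the decoder
restores resolution with index-preserving max unpooling, so odd sizes
(447 -> 223 -> 111 -> 55 -> 27) round-trip exactly.

This module only *describes* the network (layer specs, shapes, parameter
counts, residual links); :mod:`vessnet.network` executes a plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

__all__ = [
    "TensorShape",
    "ConvLayerSpec",
    "ResidualLink",
    "BlockSpec",
    "NetworkPlan",
    "plan_vessnet",
    "conv_param_count",
    "bn_param_count",
    "infer_shapes",
    "describe_plan",
]


@dataclass(frozen=True)
class TensorShape:
    """Spatial height/width plus channel count of an activation map."""

    height: int
    width: int
    channels: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0 or self.channels <= 0:
            raise ValueError(f"non-positive tensor shape: {self}")

    def __str__(self) -> str:  # table convention: W x H x C
        return f"{self.width} × {self.height} × {self.channels}"


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolution layer (always followed by batch normalization)."""

    name: str
    kernel: tuple[int, int]
    in_channels: int
    out_channels: int
    has_bn: bool = True
    relu_after: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ((3, 3), (1, 1)):
            raise ValueError(f"{self.name}: unsupported kernel {self.kernel}")
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise ValueError(f"{self.name}: non-positive channel count")


@dataclass(frozen=True)
class ResidualLink:
    """A skip path: projection (1x1 conv + BN) or identity."""

    link_id: str
    kind: Literal["projection", "identity"]
    source: str  # named tensor tap
    target: str  # named add point
    projection: ConvLayerSpec | None = None

    def __post_init__(self) -> None:
        if self.kind == "projection" and self.projection is None:
            raise ValueError(f"{self.link_id}: projection link needs a conv spec")
        if self.kind == "identity" and self.projection is not None:
            raise ValueError(f"{self.link_id}: identity link cannot project")


@dataclass(frozen=True)
class BlockSpec:
    """One encoder or decoder convolution block (two 3x3 convs)."""

    block_id: str
    role: Literal["encoder", "decoder"]
    layers: tuple[ConvLayerSpec, ConvLayerSpec]
    has_irsp: bool
    irsp: ConvLayerSpec | None = None
    pool_or_unpool: Literal["pool", "unpool", "none"] = "none"

    def __post_init__(self) -> None:
        if len(self.layers) != 2:
            raise ValueError(f"{self.block_id}: a block holds exactly two convs")
        if self.has_irsp != (self.irsp is not None):
            raise ValueError(f"{self.block_id}: has_irsp/irsp mismatch")


@dataclass(frozen=True)
class NetworkPlan:
    blocks: tuple[BlockSpec, ...]
    links: tuple[ResidualLink, ...]
    input_shape: TensorShape
    num_classes: int

    def conv_layers(self) -> list[ConvLayerSpec]:
        """All 3x3 convolution layers in execution order (excludes projections)."""
        return [layer for b in self.blocks for layer in b.layers]

    def all_layers(self) -> list[ConvLayerSpec]:
        """Every parameterized conv layer, projections included, in order."""
        out: list[ConvLayerSpec] = []
        for b in self.blocks:
            out.extend(b.layers)
            if b.irsp is not None:
                out.append(b.irsp)
        return out

    def layer(self, name: str) -> ConvLayerSpec:
        for spec in self.all_layers():
            if spec.name == name:
                return spec
        raise KeyError(name)

    def to_dict(self) -> dict:
        return asdict(self)


def conv_param_count(spec: ConvLayerSpec) -> int:
    """Trainable parameters of the convolution itself: (kh*kw*Cin + 1)*Cout."""
    kh, kw = spec.kernel
    return (kh * kw * spec.in_channels + 1) * spec.out_channels


def bn_param_count(spec: ConvLayerSpec) -> int:
    """Trainable BN parameters: per-channel scale + shift (running stats excluded)."""
    return 2 * spec.out_channels


def plan_vessnet(
    input_shape: TensorShape,
    num_classes: int = 2,
    base_channels: int = 64,
) -> NetworkPlan:
    """Build the standard 4+4-block Vess-Net plan.

    Parameters
    ----------
    input_shape
        RGB input; height and width must be at least 16 so four pooling
        stages keep a non-degenerate bottom map.
    num_classes
        Output channels of the final 3x3 convolution (2 = vessel/background).
    base_channels
        Width of the first encoder block; deeper blocks double it.  The
        reference network uses 64; smaller values give a width-scaled network
        with identical topology.
    """
    if input_shape.channels != 3:
        raise ValueError("input must have 3 channels (RGB)")
    if input_shape.height < 16 or input_shape.width < 16:
        raise ValueError("input spatial dims must be >= 16")
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    if base_channels < 1:
        raise ValueError("base_channels must be >= 1")

    b = base_channels
    widths = [b, 2 * b, 4 * b, 8 * b]  # per encoder block

    blocks: list[BlockSpec] = []
    links: list[ResidualLink] = []

    # --- encoder ---------------------------------------------------------
    in_ch = input_shape.channels
    for i in range(1, 5):
        out_ch = widths[i - 1]
        first = ConvLayerSpec(f"ECon-{i}_1", (3, 3), in_ch, out_ch, relu_after=True)
        # second conv: BN only when its output feeds a residual add (blocks 2-4)
        second = ConvLayerSpec(
            f"ECon-{i}_2", (3, 3), out_ch, out_ch, relu_after=(i == 1)
        )
        irsp = None
        if i > 1:
            irsp = ConvLayerSpec(
                f"IRSP-{i - 1}", (1, 1), in_ch, out_ch, relu_after=False
            )
            links.append(
                ResidualLink(
                    f"IRSP-{i - 1}",
                    "projection",
                    source=f"ECB-{i}.input",
                    target=f"ECB-{i}.add",
                    projection=irsp,
                )
            )
        blocks.append(
            BlockSpec(
                f"ECB-{i}",
                "encoder",
                (first, second),
                has_irsp=irsp is not None,
                irsp=irsp,
                pool_or_unpool="pool",
            )
        )
        in_ch = out_ch

    # outer identity links: encoder first-ReLU tap -> decoder add point
    for i in range(1, 5):
        links.append(
            ResidualLink(
                f"ORSP-{i}",
                "identity",
                source=f"ECB-{i}.relu1",
                target=f"DCB-{i}.orsp_add",
            )
        )

    # --- decoder (mirror: DCB-4 .. DCB-1) --------------------------------
    for j in range(4, 0, -1):
        ch = widths[j - 1]
        down = widths[j - 2] if j > 1 else num_classes
        first = ConvLayerSpec(f"DCon-{j}_2", (3, 3), ch, ch, relu_after=True)
        second = ConvLayerSpec(
            f"DCon-{j}_1", (3, 3), ch, down, relu_after=(j == 1)
        )
        irsp = None
        if j > 1:
            irsp = ConvLayerSpec(f"IRSP-{8 - j}", (1, 1), ch, down, relu_after=False)
            links.append(
                ResidualLink(
                    f"IRSP-{8 - j}",
                    "projection",
                    source=f"DCB-{j}.input",
                    target=f"DCB-{j}.add",
                    projection=irsp,
                )
            )
        blocks.append(
            BlockSpec(
                f"DCB-{j}",
                "decoder",
                (first, second),
                has_irsp=irsp is not None,
                irsp=irsp,
                pool_or_unpool="unpool",
            )
        )

    plan = NetworkPlan(
        blocks=tuple(blocks),
        links=tuple(links),
        input_shape=input_shape,
        num_classes=num_classes,
    )
    infer_shapes(plan)  # validates residual-add compatibility
    return plan


def _halve(x: int) -> int:
    return x // 2


def infer_shapes(plan: NetworkPlan) -> dict[str, TensorShape]:
    """Shape of every named activation in the plan.

    3x3 convs preserve spatial dims (single-pixel zero padding, stride 1);
    pooling floor-halves; unpooling restores the matching pre-pool shape.
    Raises ``ValueError`` if any residual add would join mismatched shapes.
    """
    shapes: dict[str, TensorShape] = {"input": plan.input_shape}
    h, w = plan.input_shape.height, plan.input_shape.width

    enc = [blk for blk in plan.blocks if blk.role == "encoder"]
    dec = [blk for blk in plan.blocks if blk.role == "decoder"]

    pre_pool: list[tuple[int, int]] = []  # per encoder block, shape before pool
    tap_shapes: dict[str, TensorShape] = {}
    for blk in enc:
        first, second = blk.layers
        shapes[first.name] = TensorShape(h, w, first.out_channels)
        tap_shapes[blk.block_id] = shapes[first.name]
        shapes[second.name] = TensorShape(h, w, second.out_channels)
        if blk.irsp is not None:
            shapes[blk.irsp.name] = TensorShape(h, w, blk.irsp.out_channels)
            if shapes[blk.irsp.name] != shapes[second.name]:
                raise ValueError(f"{blk.block_id}: residual add shape mismatch")
        pre_pool.append((h, w))
        h, w = _halve(h), _halve(w)
        shapes[f"Pool-{blk.block_id[-1]}"] = TensorShape(h, w, second.out_channels)

    for blk in dec:
        j = int(blk.block_id[-1])
        h, w = pre_pool[j - 1]  # unpool restores the recorded shape
        first, second = blk.layers
        shapes[f"Unpool-{j}"] = TensorShape(h, w, first.in_channels)
        shapes[first.name] = TensorShape(h, w, first.out_channels)
        tap = tap_shapes[f"ECB-{j}"]
        if shapes[first.name] != tap:
            raise ValueError(
                f"{blk.block_id}: identity add shape mismatch "
                f"({shapes[first.name]} vs encoder tap {tap})"
            )
        shapes[second.name] = TensorShape(h, w, second.out_channels)
        if blk.irsp is not None:
            shapes[blk.irsp.name] = TensorShape(h, w, blk.irsp.out_channels)
            if shapes[blk.irsp.name] != shapes[second.name]:
                raise ValueError(f"{blk.block_id}: residual add shape mismatch")

    shapes["output"] = TensorShape(
        plan.input_shape.height, plan.input_shape.width, plan.num_classes
    )
    return shapes


def describe_plan(plan: NetworkPlan | None) -> str:
    """Plain-text table of every layer: shape and parameter counts.

    Mirrors the conventional architecture-table layout ("conv + BN" parameter
    columns, W x H x C shapes) and appends grand totals.
    """
    header = f"{'Block':8}  {'Layer':10}  {'Output (W × H × C)':22}  {'Parameters (conv + BN)':>24}"
    lines = [header, "-" * len(header)]
    if plan is None:
        return "\n".join(lines)

    shapes = infer_shapes(plan)
    total_conv = 0
    total_bn = 0

    def row(block_id: str, spec: ConvLayerSpec) -> str:
        nonlocal total_conv, total_bn
        c = conv_param_count(spec)
        n = bn_param_count(spec)
        total_conv += c
        total_bn += n
        return (
            f"{block_id:8}  {spec.name:10}  {str(shapes[spec.name]):22}  "
            f"{f'{c:,} + {n}':>24}"
        )

    for blk in plan.blocks:
        first, second = blk.layers
        if blk.pool_or_unpool == "unpool":  # dataflow: unpool precedes the block
            j = blk.block_id[-1]
            lines.append(
                f"{blk.block_id:8}  {f'Unpool-{j}':10}  {str(shapes[f'Unpool-{j}']):22}  {'-':>24}"
            )
        lines.append(row(blk.block_id, first))
        if blk.irsp is not None:
            lines.append(row(blk.block_id, blk.irsp))
        lines.append(row(blk.block_id, second))
        if blk.pool_or_unpool == "pool":
            i = blk.block_id[-1]
            lines.append(
                f"{blk.block_id:8}  {f'Pool-{i}':10}  {str(shapes[f'Pool-{i}']):22}  {'-':>24}"
            )
    lines.append("-" * len(header))
    lines.append(
        f"{'Total':8}  {'':10}  {'':22}  {f'{total_conv:,} + {total_bn:,}':>24}"
    )
    return "\n".join(lines)
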