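"""Declarative CNN architecture specs and closed-form parameter counting.

A convolution layer with a k_h×k_w kernel mapping c_in to c_out channels
carries ``k_h·k_w·c_in·c_out`` weights (+ c_out biases); a fully connected
layer carries ``n_in·n_out`` (+ n_out).  Pooling and flattening carry none.
Summing these over an ordered layer list reproduces the published parameter
counts of the reference architectures without instantiating any network.

Shipped specs: AlexNet (single-stack, ungrouped — 62,378,344 parameters),
VGG16 (138,357,544), GoogLeNet (inception-v1), and LeNet-5.  Every spec
passes an explicit shape-propagation check from its input extent.

Note on the reference counts: only the ungrouped AlexNet variant yields the
commonly cited 62.4M total, and inception-v1's canonical count (~7.0M) is
far below figures sometimes quoted for later Inception revisions; the
GoogLeNet and LeNet totals here are informational, derived strictly from
the canonical layer tables.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidSpecError

__all__ = [
    "LayerSpec",
    "conv",
    "fc",
    "pool",
    "flatten",
    "inception",
    "ArchitectureSpec",
    "count_parameters",
    "layer_table",
    "spec_alexnet",
    "spec_vgg16",
    "spec_googlenet",
    "spec_lenet",
    "ARCHITECTURES",
]


@dataclass(frozen=True)
class LayerSpec:
    """One layer, described by kind plus the fields that kind needs."""

    kind: str                      # conv | fc | pool | flatten | inception_block
    name: str = ""
    in_channels: int = 0
    out_channels: int = 0
    kernel_h: int = 0
    kernel_w: int = 0
    stride: int = 1
    padding: int = 0
    bias: bool = True
    in_features: int = 0
    out_features: int = 0
    window: int = 0
    # inception branch widths: 1x1; 3x3-reduce, 3x3; 5x5-reduce, 5x5; pool-proj
    branches: tuple = ()


def conv(in_channels, out_channels, kernel, stride=1, padding=0, bias=True, name=""):
    kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
    return LayerSpec(kind="conv", name=name or f"conv{kh}x{kw}",
                     in_channels=in_channels, out_channels=out_channels,
                     kernel_h=kh, kernel_w=kw, stride=stride, padding=padding,
                     bias=bias)


def fc(in_features, out_features, bias=True, name=""):
    return LayerSpec(kind="fc", name=name or "fc", in_features=in_features,
                     out_features=out_features, bias=bias)


def pool(window, stride=None, padding=0, name=""):
    return LayerSpec(kind="pool", name=name or f"pool{window}",
                     window=window, stride=stride or window, padding=padding)


def flatten(name="flatten"):
    return LayerSpec(kind="flatten", name=name)


def inception(in_channels, n1x1, r3x3, n3x3, r5x5, n5x5, npool, name="inception"):
    """Inception-v1 block: parallel 1×1, 1×1→3×3, 1×1→5×5 and pool→1×1
    branches, concatenated along channels."""
    return LayerSpec(kind="inception_block", name=name, in_channels=in_channels,
                     out_channels=n1x1 + n3x3 + n5x5 + npool,
                     branches=(n1x1, r3x3, n3x3, r5x5, n5x5, npool))


@dataclass(frozen=True)
class ArchitectureSpec:
    """Named, ordered layer list with an input extent for shape checking."""

    name: str
    input: tuple[int, int, int]            # (height, width, channels)
    layers: tuple[LayerSpec, ...]
    n_classes: int = 1000

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        propagate_shapes(self)            # raises on inconsistent chaining


def _conv_out(extent: int, kernel: int, stride: int, padding: int) -> int:
    out = (extent + 2 * padding - kernel) // stride + 1
    if out < 1:
        raise InvalidSpecError("layer output extent collapsed below 1")
    return out


def propagate_shapes(spec: ArchitectureSpec) -> list[tuple]:
    """Chain output shapes through the layer list; raises InvalidSpecError
    on any mismatch.  Returns the shape after every layer."""
    h, w, c = spec.input
    flat: int | None = None
    shapes: list[tuple] = []
    for layer in spec.layers:
        if layer.kind == "conv":
            if flat is not None:
                raise InvalidSpecError(f"{layer.name}: conv after flatten")
            if layer.in_channels != c:
                raise InvalidSpecError(
                    f"{layer.name}: expects {layer.in_channels} channels, gets {c}")
            h = _conv_out(h, layer.kernel_h, layer.stride, layer.padding)
            w = _conv_out(w, layer.kernel_w, layer.stride, layer.padding)
            c = layer.out_channels
        elif layer.kind == "inception_block":
            if layer.in_channels != c:
                raise InvalidSpecError(
                    f"{layer.name}: expects {layer.in_channels} channels, gets {c}")
            c = layer.out_channels
        elif layer.kind == "pool":
            if flat is not None:
                raise InvalidSpecError(f"{layer.name}: pool after flatten")
            h = _conv_out(h, layer.window, layer.stride, layer.padding)
            w = _conv_out(w, layer.window, layer.stride, layer.padding)
        elif layer.kind == "flatten":
            flat = h * w * c
        elif layer.kind == "fc":
            if flat is None:
                raise InvalidSpecError(f"{layer.name}: fc before flatten")
            if layer.in_features != flat:
                raise InvalidSpecError(
                    f"{layer.name}: expects {layer.in_features} features, gets {flat}")
            flat = layer.out_features
        else:
            raise InvalidSpecError(f"unknown layer kind {layer.kind!r}")
        shapes.append((h, w, c) if flat is None else (flat,))
    return shapes


def _layer_params(layer: LayerSpec) -> int:
    if layer.kind == "conv":
        p = layer.kernel_h * layer.kernel_w * layer.in_channels * layer.out_channels
        return p + (layer.out_channels if layer.bias else 0)
    if layer.kind == "fc":
        return layer.in_features * layer.out_features + (layer.out_features if layer.bias else 0)
    if layer.kind == "inception_block":
        n1, r3, n3, r5, n5, npool = layer.branches
        cin = layer.in_channels
        total = 0
        for cin_b, cout_b, k in [(cin, n1, 1), (cin, r3, 1), (r3, n3, 3),
                                 (cin, r5, 1), (r5, n5, 5), (cin, npool, 1)]:
            total += k * k * cin_b * cout_b + cout_b
        return total
    return 0


def count_parameters(spec: ArchitectureSpec) -> int:
    """Total trainable parameters of a shape-consistent architecture spec."""
    propagate_shapes(spec)
    return sum(_layer_params(layer) for layer in spec.layers)


def layer_table(spec: ArchitectureSpec) -> list[dict]:
    """Per-layer accounting: name, kind, output shape, parameter count."""
    shapes = propagate_shapes(spec)
    return [
        {"layer": layer.name, "kind": layer.kind,
         "output_shape": "x".join(map(str, shape)),
         "parameters": _layer_params(layer)}
        for layer, shape in zip(spec.layers, shapes)
    ]


def weighted_depth(spec: ArchitectureSpec) -> int:
    """Number of weight-bearing layers, counting an inception block as 2
    (the reduce and main stages of its deepest branch)."""
    depth = 0
    for layer in spec.layers:
        if layer.kind in ("conv", "fc"):
            depth += 1
        elif layer.kind == "inception_block":
            depth += 2
    return depth


def spec_alexnet() -> ArchitectureSpec:
    """AlexNet as a single ungrouped stack: 5 conv + 3 fc layers.

    Input 227×227×3; conv filters 96, 256, 384, 384, 256 with kernels
    11, 5, 3, 3, 3; the feature map entering the classifier is 6×6×256.
    """
    return ArchitectureSpec(
        name="alexnet", input=(227, 227, 3), n_classes=1000,
        layers=(
            conv(3, 96, 11, stride=4, name="conv1"),
            pool(3, 2, name="pool1"),
            conv(96, 256, 5, padding=2, name="conv2"),
            pool(3, 2, name="pool2"),
            conv(256, 384, 3, padding=1, name="conv3"),
            conv(384, 384, 3, padding=1, name="conv4"),
            conv(384, 256, 3, padding=1, name="conv5"),
            pool(3, 2, name="pool5"),
            flatten(),
            fc(9216, 4096, name="fc6"),
            fc(4096, 4096, name="fc7"),
            fc(4096, 1000, name="fc8"),
        ))


def spec_vgg16() -> ArchitectureSpec:
    """VGG16: thirteen 3×3 stride-1 conv layers in five blocks + 3 fc."""
    widths = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]
    layers: list[LayerSpec] = []
    cin = 3
    for b, (cout, reps) in enumerate(widths, start=1):
        for r in range(1, reps + 1):
            layers.append(conv(cin, cout, 3, padding=1, name=f"conv{b}_{r}"))
            cin = cout
        layers.append(pool(2, 2, name=f"pool{b}"))
    layers += [flatten(), fc(7 * 7 * 512, 4096, name="fc6"),
               fc(4096, 4096, name="fc7"), fc(4096, 1000, name="fc8")]
    return ArchitectureSpec(name="vgg16", input=(224, 224, 3), layers=tuple(layers))


def spec_googlenet() -> ArchitectureSpec:
    """GoogLeNet (inception-v1): 22 weight-bearing layers.

    Canonical block table; auxiliary classifiers excluded.  The parameter
    total is informational — see the module docstring.
    """
    return ArchitectureSpec(
        name="googlenet", input=(224, 224, 3), n_classes=1000,
        layers=(
            conv(3, 64, 7, stride=2, padding=3, name="conv1"),
            pool(3, 2, padding=1, name="pool1"),
            conv(64, 64, 1, name="conv2_reduce"),
            conv(64, 192, 3, padding=1, name="conv2"),
            pool(3, 2, padding=1, name="pool2"),
            inception(192, 64, 96, 128, 16, 32, 32, name="inception3a"),
            inception(256, 128, 128, 192, 32, 96, 64, name="inception3b"),
            pool(3, 2, padding=1, name="pool3"),
            inception(480, 192, 96, 208, 16, 48, 64, name="inception4a"),
            inception(512, 160, 112, 224, 24, 64, 64, name="inception4b"),
            inception(512, 128, 128, 256, 24, 64, 64, name="inception4c"),
            inception(512, 112, 144, 288, 32, 64, 64, name="inception4d"),
            inception(528, 256, 160, 320, 32, 128, 128, name="inception4e"),
            pool(3, 2, padding=1, name="pool4"),
            inception(832, 256, 160, 320, 32, 128, 128, name="inception5a"),
            inception(832, 384, 192, 384, 48, 128, 128, name="inception5b"),
            pool(7, 1, name="avgpool"),
            flatten(),
            fc(1024, 1000, name="fc"),
        ))


def spec_lenet() -> ArchitectureSpec:
    """LeNet-5: 2 conv + 3 fc on 32×32 grayscale input."""
    return ArchitectureSpec(
        name="lenet", input=(32, 32, 1), n_classes=10,
        layers=(
            conv(1, 6, 5, name="conv1"),
            pool(2, 2, name="pool1"),
            conv(6, 16, 5, name="conv2"),
            pool(2, 2, name="pool2"),
            flatten(),
            fc(400, 120, name="fc3"),
            fc(120, 84, name="fc4"),
            fc(84, 10, name="fc5"),
        ))


ARCHITECTURES = {
    "alexnet": spec_alexnet,
    "vgg16": spec_vgg16,
    "googlenet": spec_googlenet,
    "lenet": spec_lenet,
}


def spec_to_dict(spec: ArchitectureSpec) -> dict:
    """JSON-serializable export of an architecture spec."""
    from dataclasses import asdict

    return {"name": spec.name, "input": list(spec.input),
            "n_classes": spec.n_classes,
            "layers": [asdict(layer) for layer in spec.layers]}
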