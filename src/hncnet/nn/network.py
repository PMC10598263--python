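"""Sequential networks with an optional late-fusion side input.

The final layer of every network here is a Dense producing one logit per
sample; the sigmoid lives in the loss/prediction code so gradients can be
computed in the numerically stable logit form.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .layers import Layer


class Network:
    """A plain sequential stack ending in a single-logit Dense layer."""

    def __init__(self, layers: list[Layer]):
        from .layers import Conv2D

        self.layers = layers
        if layers and isinstance(layers[0], Conv2D):
            layers[0].skip_input_grad = True

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x, clinical=None, training=False, rng=None):
        h = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            h = layer.forward(h, training=training, rng=rng)
        return h[:, 0]

    def backward(self, dlogit):
        dy = dlogit[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def predict_proba(self, x, clinical=None):
        return expit(self.forward_logits(x, clinical=clinical, training=False))

    # -- parameter access ---------------------------------------------------
    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(zip(layer.params, layer.grads, layer.weight_flags))
        return out

    def n_params(self) -> int:
        return int(sum(layer.n_params() for layer in self.layers))

    def get_weights(self):
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights):
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list does not match network structure")
        for dst, src in zip(flat, weights):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src


class FusionNetwork(Network):
    """Image trunk + fully connected head, with a clinical feature vector
    concatenated to the input of one chosen FC layer.

    ``fc_index`` is 1-based over the Dense layers of the head; the widened
    Dense layer owns the extra ``clinical_dim`` input columns, so the
    parameter increase over the image-only network is exactly
    ``clinical_dim * fan_out`` of that layer.
    """

    def __init__(self, trunk: list[Layer], head: list[Layer], inject_at_fc: int, clinical_dim: int):
        from .layers import Dense

        self.trunk = trunk
        self.head = head
        self.inject_at_fc = inject_at_fc
        self.clinical_dim = clinical_dim
        dense_count = 0
        self._inject_layer_pos = None
        for i, layer in enumerate(head):
            if isinstance(layer, Dense):
                dense_count += 1
                if dense_count == inject_at_fc:
                    self._inject_layer_pos = i
        if self._inject_layer_pos is None:
            raise ValueError(f"inject_at_fc={inject_at_fc} exceeds the {dense_count} FC layers")
        super().__init__(trunk + head)

    def forward_logits(self, x, clinical=None, training=False, rng=None):
        if clinical is None:
            raise ValueError("FusionNetwork requires a clinical feature matrix")
        clinical = np.asarray(clinical, dtype=np.float32)
        if clinical.shape[1] != self.clinical_dim:
            raise ValueError(f"expected {self.clinical_dim} clinical features, got {clinical.shape[1]}")
        h = np.asarray(x, dtype=np.float32)
        for layer in self.trunk:
            h = layer.forward(h, training=training, rng=rng)
        for i, layer in enumerate(self.head):
            if i == self._inject_layer_pos:
                h = np.concatenate([h, clinical], axis=1)
            h = layer.forward(h, training=training, rng=rng)
        self._pre_inject_dim = None
        return h[:, 0]

    def backward(self, dlogit):
        dy = dlogit[:, None].astype(np.float32)
        for i in range(len(self.head) - 1, -1, -1):
            dy = self.head[i].backward(dy)
            if i == self._inject_layer_pos:
                dy = dy[:, : dy.shape[1] - self.clinical_dim]
        for layer in reversed(self.trunk):
            dy = layer.backward(dy)
        return dy
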