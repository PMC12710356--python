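"""Optional adapter exposing a real protein-language-model backend.

Loads published ESM2 weights behind the same frozen-backend contract as
the k-mer stub. Requires the optional ``fair-esm`` + ``torch`` packages
and a local copy of the weights; nothing in the package or its tests
depends on it.
"""

from __future__ import annotations

import numpy as np

from .embeddings import EmbeddingBackend


def esm2_backend(model_name: str = "esm2_t33_650M_UR50D") -> EmbeddingBackend:
    try:
        import esm  # type: ignore
        import torch  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the esm2 backend needs the optional 'fair-esm' and 'torch' packages"
        ) from exc

    model, alphabet = getattr(esm.pretrained, model_name)()
    model.eval()
    converter = alphabet.get_batch_converter()
    layer = model.num_layers

    def embed_fn(sequence: str) -> np.ndarray:  # pragma: no cover
        _, _, tokens = converter([("seq", sequence)])
        with torch.no_grad():
            out = model(tokens, repr_layers=[layer])
        reps = out["representations"][layer][0, 1 : len(sequence) + 1]
        return reps.numpy().astype(float)

    return EmbeddingBackend(name=model_name, dim=model.embed_dim, embed_fn=embed_fn)
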