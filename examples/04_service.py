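"""Serve suggestions over HTTP and call the endpoint.

Trains a tiny model, starts the WSGI service on an ephemeral port and
issues a real GET request against /api/v1/semanticsuggestion/<query>.
"""

import json
import threading
import urllib.request
from wsgiref.simple_server import make_server

from semsuggest import (
    SynonymSpec,
    TrainingConfig,
    build_huffman,
    build_vocabulary,
    create_app,
    generate_synonym_corpus,
    train,
)

groups = tuple(frozenset(f"syn{g}_{i}" for i in range(3)) for g in range(3))
docs = generate_synonym_corpus(SynonymSpec(groups=groups, n_docs=300, seed=1))
tokens = [d.text.split() for d in docs]
vocab = build_vocabulary(tokens, min_count=1)
model = train(tokens, vocab, build_huffman(vocab),
              TrainingConfig(dim=16, window=3, epochs=3, seed=1))

server = make_server("127.0.0.1", 0, create_app(model, k=5))
port = server.server_address[1]
threading.Thread(target=server.serve_forever, daemon=True).start()

url = f"http://127.0.0.1:{port}/api/v1/semanticsuggestion/syn0_0"
with urllib.request.urlopen(url) as resp:
    payload = json.loads(resp.read().decode("utf-8"))
server.shutdown()

print("GET", url)
print(json.dumps(payload, indent=2))
# the JSON object has the single key "suggestions" with at most five
# alternative queries, ranked by cosine similarity to the request query
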