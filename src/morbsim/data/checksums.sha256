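541d04b54375c7d08e80c72ddaba8a249181260077017d98c32138e4993a5b51  conditions.tsv
542288322bc42eb736df39d505e22ef332730bf74d15a9b29368a2ebfcc5f066  risk_links.tsv
6ba7242d0a5269fc31bd2bef4017992fe1a244eec9dd3f641acf27a0628b8c82  parent_links.tsv
6e9e5cef7003146950a63c6bab8be1693ce512fc85e975416035b32b539ce080  tmrel.tsv
62993daf89ec870e89fce37e97436766e8c0e1e0ef5c3ca435dbcc49f289aa61  other_mortality.tsv
eadbadd60ea3f256f02ff7844911a97a30d7e8f9b7d3c8cb37b3a368c1d72ab5  mediation.tsv
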