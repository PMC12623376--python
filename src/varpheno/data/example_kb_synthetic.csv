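Symptom,Dystroglycanopathy,Duchenne muscular dystrophy,Spinal muscular atrophy,Myotonic dystrophy,Charcot-Marie-Tooth disease,Nemaline myopathy,Mitochondrial myopathy,Emery-Dreifuss muscular dystrophy
ophthalmoplegia,+,,,,,,+,
facial muscle weakness,+,,,+,,+,,
hypotonia,+,,+,,,+,,
white matter signal abnormalities,+,,,,,,,
dysmorphism,+,,,,,,,
growth failure,+,,,,,,+,
spasticity,+,,,,,,,
spastic paralysis of legs,+,,,,,,,
muscle weakness,,+,+,+,+,+,+,+
calf hypertrophy,,+,,,,,,
elevated creatine kinase,,+,,,,,,+
frequent falls,,+,,+,,,,
tongue fasciculations,,,+,,,,,
respiratory insufficiency,,,+,,,+,,
myotonia,,,,+,,,,
cataract,,,,+,,,,
foot drop,,,,,+,,,
distal sensory loss,,,,,+,,,
exercise intolerance,,,,,,,+,
joint contractures,,,,,,,,+
cardiac involvement,,+,,+,,,,+
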