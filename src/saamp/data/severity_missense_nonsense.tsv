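mutation	mutation_printed	class	severities	low_reliability	source
Y76C	Y76C	missense	mild	false	missense_nonsense
M504T	M504T	missense	intermediate	false	missense_nonsense
V620F	V620F	missense	severe	false	missense_nonsense
R89W	R89W	missense	mild	false	missense_nonsense
L535F	L535F	missense	intermediate	false	missense_nonsense
R628P	R628P	missense	severe	false	missense_nonsense
R89Q	R89Q	missense	mild,intermediate	false	missense_nonsense
R619G	R619G	missense	intermediate	false	missense_nonsense
X654C	X654C	missense	severe	false	missense_nonsense
A160D	A160D	missense	mild,intermediate	false	missense_nonsense
W626R	W626R	missense	intermediate	false	missense_nonsense
L421P	L421P	missense	unknown	false	missense_nonsense
C205Y	C205Y	missense	mild	false	missense_nonsense
X654G	X654G	missense	intermediate	false	missense_nonsense
L578Q	L578Q	missense	unknown	false	missense_nonsense
G219E	G219E	missense	mild,intermediate	false	missense_nonsense
X654R	X654R	missense	intermediate,severe	false	missense_nonsense
G168V	G168 V	missense	unknown	false	missense_nonsense
H240R	H240R	missense	mild	false	missense_nonsense
M1T	M1 T	missense	severe	false	missense_nonsense
F52L	F52 L	missense	unknown	false	missense_nonsense
E276K	E276K	missense	mild,intermediate	false	missense_nonsense
G51D	G51D	missense	severe	false	missense_nonsense
L396P	L396P	missense	unknown	false	missense_nonsense
W306L	W306 L	missense	mild,intermediate	false	missense_nonsense
A75T	A75T	missense	severe	false	missense_nonsense
P533R	P533R	missense	unknown	false	missense_nonsense
A319V	A319V	missense	mild,intermediate	false	missense_nonsense
T103P	T103P	missense	severe	false	missense_nonsense
H33P	H33P	missense	unknown	false	missense_nonsense
L346R	L346R	missense	mild,intermediate	false	missense_nonsense
M133I	M133I	missense	severe	false	missense_nonsense
A79V	A79V	missense	unknown	false	missense_nonsense
N348K	N348 K	missense	mild	true	missense_nonsense
T141S	T141S	missense	severe	false	missense_nonsense
G197S	G197S	missense	unknown	false	missense_nonsense
N350I	N350I	missense	mild,intermediate	false	missense_nonsense
F177S	F177S	missense	severe	false	missense_nonsense
W41X	W41X	nonsense	severe	false	missense_nonsense
Q380R	Q380R	missense	mild,intermediate	false	missense_nonsense
E182D	E182D	missense	severe	false	missense_nonsense
C53X	C53X	nonsense	severe	false	missense_nonsense
R383H	R383H	missense	mild,intermediate	false	missense_nonsense
E182K	E182K	missense	severe	false	missense_nonsense
Q60X	Q60X	nonsense	severe	false	missense_nonsense
T388R	T388R	missense	mild	false	missense_nonsense
P183R	P183R	missense	severe	false	missense_nonsense
Q63X	Q63X	nonsense	severe	false	missense_nonsense
S423R	S423R	missense	mild,intermediate	false	missense_nonsense
D203N	D203N	missense	severe	false	missense_nonsense
Y64X	Y64X	nonsense	severe	false	missense_nonsense
R492P	R492P	missense	mild	false	missense_nonsense
G208D	G208D	missense	severe	false	missense_nonsense
Q70X	Q70X	nonsense	severe	false	missense_nonsense
S633L	S633 L	missense	mild,intermediate	false	missense_nonsense
G208V	G208 V	missense	severe	false	missense_nonsense
Y167X	Y167X	nonsense	severe	false	missense_nonsense
M1I	M1I	missense	intermediate	false	missense_nonsense
L218P	L218P	missense	severe	false	missense_nonsense
Y201X	Y201X	nonsense	severe	false	missense_nonsense
A75P	A75P	missense	intermediate	false	missense_nonsense
L237R	L237R	missense	severe	false	missense_nonsense
E274X	E274X	nonsense	severe	false	missense_nonsense
H82P	H82P	missense	intermediate	false	missense_nonsense
L238R	L238R	missense	severe	false	missense_nonsense
E299X	E299X	nonsense	severe	false	missense_nonsense
G84R	G84R	missense	intermediate	true	missense_nonsense
I270S	I270S	missense	severe	false	missense_nonsense
Q310X	Q310X	nonsense	severe	false	missense_nonsense
E178K	E178K	missense	intermediate	false	missense_nonsense
L308P	L308P	missense	severe	false	missense_nonsense
Y343X	Y343X	nonsense	severe	false	missense_nonsense
T179R	T179R	missense	intermediate,severe	false	missense_nonsense
D315Y	D315Y	missense	severe	false	missense_nonsense
W402X	W402X	nonsense	severe	false	missense_nonsense
F188L	F188 L	missense	intermediate	true	missense_nonsense
A327P	A327P	missense	severe	false	missense_nonsense
E404X	E404X	nonsense	severe	false	missense_nonsense
G197D	G197D	missense	intermediate	false	missense_nonsense
D349N	D349N	missense	severe	false	missense_nonsense
W420X	W420X	nonsense	severe	false	missense_nonsense
L238Q	L238Q	missense	intermediate	false	missense_nonsense
D349Y	D349Y	missense	severe	false	missense_nonsense
Q561X	Q561X	nonsense	severe	false	missense_nonsense
S260F	S260F	missense	intermediate	true	missense_nonsense
R363C	R363C	missense	severe	false	missense_nonsense
Y581X	Y581X	nonsense	severe	false	missense_nonsense
G265R	G265R	missense	intermediate	false	missense_nonsense
T366P	T366P	missense	severe	false	missense_nonsense
Q584X	Q584X	nonsense	severe	false	missense_nonsense
R363H	R363H	missense	intermediate	false	missense_nonsense
T374N	T374 N	missense	severe	false	missense_nonsense
R619X	R619X	nonsense	severe	false	missense_nonsense
T364M	T364 M	missense	intermediate	false	missense_nonsense
P385R	P385R	missense	severe	false	missense_nonsense
R621X	R621X	nonsense	severe	false	missense_nonsense
A436P	A436P	missense	intermediate	false	missense_nonsense
R489P	R489P	missense	severe	false	missense_nonsense
W626X	W626X	nonsense	severe	false	missense_nonsense
G409R	G409R	missense	severe	false	missense_nonsense
P496R	P496R	missense	severe	false	missense_nonsense
R628X	R628X	nonsense	severe	false	missense_nonsense
L490P	L490P	missense	intermediate	false	missense_nonsense
P533L	P533L	missense	severe	false	missense_nonsense
P496L	P496L	missense	intermediate	false	missense_nonsense
F602I	F602I	missense	severe	false	missense_nonsense
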