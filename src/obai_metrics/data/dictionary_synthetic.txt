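# Synthetic reference dictionary: a constructed wordlist used by default for
# neologism/paraphasia candidate detection and lemma validation. It extends
# the bundled easy-word list with inflected and less common forms. It is not
# an exhaustive English lexicon; supply your own dictionary for clinical use.
able
added
alligator
alphabet
always
am
analysis
analyzed
answered
appeared
asks
assess
assessed
assessment
assignment
assignments
avocado
balls
barks
bears
became
becomes
bedrooms
bells
belongs
bikes
bike
bottles
bought
bowls
boxes
branch
branches
bridges
brings
brushes
brush
buses
bushes
bush
calls
carried
carries
catches
chairs
changed
chances
chases
chase
chased
cities
classes
climbed
climbs
clocks
closed
closes
clouds
coats
colors
comes
converted
convert
converts
cooks
corners
covered
covers
cows
cries
cups
cuts
dances
decorate
decorated
decorates
diligent
diligently
dishes
dives
dive
doctors
doors
draws
dreams
dresses
drinks
drives
drops
ducks
ears
edges
edge
editor
editors
ends
enjoys
enjoy
enjoyed
faces
falls
farmers
farms
feeds
feels
fences
fields
fills
fingers
finished
finishes
fires
fixes
floors
flies
follows
followed
forests
forgets
foxes
friends
frogs
fruits
games
gardens
gates
gets
gives
glasses
goats
grows
hats
heads
hears
hearts
helicopter
helps
hens
hides
hills
hits
hit
holds
holes
homes
hops
hoped
hopes
horses
hours
houses
hurries
industrious
input
jumps
keeps
kings
kitchens
kites
kittens
kicks
kick
kicked
knows
ladies
lakes
lamps
lamp
lands
laughs
laughed
learns
learned
leaves
legs
letters
lights
likes
lines
lions
lists
list
listens
listened
lives
looks
loves
lunches
makes
markets
meals
meets
minutes
misses
moments
monkeys
moons
mountains
mouths
moves
moved
names
named
necks
needs
needed
nests
nights
noises
notes
numbers
nuts
opens
oranges
pages
pages
pairs
pans
papers
parks
parked
parts
parties
passes
passed
paws
pens
pets
picks
pictures
pieces
pies
pigs
places
plans
planned
plants
planted
plays
points
pointed
ponds
ponies
prepares
prepare
prepared
professor
professors
pulls
pulled
puppies
pushes
pushed
puts
queens
rabbits
races
rains
rained
reaches
reached
reads
rides
rings
rivers
roads
rocks
rolls
rolled
roofs
rooms
ropes
runs
schools
seas
seats
seeds
sends
sheets
sheet
shines
ships
shoes
shops
shows
showed
sides
sings
sisters
sits
sleeping
smiles
smiled
songs
sounds
sounded
soups
spots
springs
stands
starts
started
stays
stayed
steps
sticks
stones
stops
stores
stories
streets
students
student
sunsets
sunset
tables
tails
teachers
tells
thanks
thanked
thinks
throws
times
towns
trains
trucks
tries
turns
turned
turtles
visits
visited
waits
waited
walks
walls
wants
washes
washed
watches
watched
waters
watered
waves
waved
wears
weeks
wheels
wishes
wished
wonders
wondered
woods
works
worked
worlds
writes
yards
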